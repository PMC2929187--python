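"""Composite motif detection: binary presence vectors + K-means.

High-coefficient (strengthening) motifs are selected from the regression
ranking; each peak becomes a binary vector of their presence calls; K-means
on those vectors groups peaks with similar motif patterns, whose shared
motif tuples are candidate composite binding elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from motifreg.features import MatchMap
from motifreg.regression import MotifRanking

DEFAULT_TAU = 0.4
DEFAULT_MIN_PAIR_FREQ = 0.5


@dataclass
class CompositeCluster:
    """One K-means cluster of peaks with its per-motif presence frequencies."""

    cluster_id: int
    peak_ids: list[str]
    motif_signature: dict[str, float]

    @property
    def size(self) -> int:
        return len(self.peak_ids)


def select_motifs(ranking: MotifRanking, tau: float = DEFAULT_TAU) -> list[str]:
    """Motifs with normalized coefficient > tau (strengthening side only)."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    selected = [mid for mid, coef, _ in ranking.rows if coef > tau]
    if not selected:
        raise ValueError(f"no motif has normalized coefficient > {tau}; lower tau")
    return selected


def kmeans_cluster(
    B: np.ndarray,
    k: int,
    seed: int,
    peak_ids: Sequence[str] | None = None,
    motif_ids: Sequence[str] | None = None,
) -> list[CompositeCluster]:
    """K-means (Euclidean on 0/1 vectors, 10 restarts) over presence rows."""
    B = np.asarray(B, dtype=float)
    n, m = B.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} peak rows")
    peak_ids = list(peak_ids) if peak_ids is not None else [f"peak_{i}" for i in range(n)]
    motif_ids = list(motif_ids) if motif_ids is not None else [f"motif_{j}" for j in range(m)]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(B)
    clusters = []
    for cid in range(k):
        rows = np.flatnonzero(labels == cid)
        signature = {mid: float(B[rows, j].mean()) if len(rows) else 0.0
                     for j, mid in enumerate(motif_ids)}
        clusters.append(CompositeCluster(
            cluster_id=cid,
            peak_ids=[peak_ids[i] for i in rows],
            motif_signature=signature,
        ))
    return clusters


def choose_k(B: np.ndarray, seed: int, k_range: Sequence[int] = range(2, 11)) -> int:
    """Pick K by the best silhouette score over a candidate range."""
    B = np.asarray(B, dtype=float)
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= B.shape[0]:
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(B)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(B, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no candidate K produced at least 2 distinct clusters")
    return best_k


def report_composites(
    clusters: Sequence[CompositeCluster],
    B: np.ndarray,
    peak_ids: Sequence[str],
    motif_ids: Sequence[str],
    min_pair_freq: float = DEFAULT_MIN_PAIR_FREQ,
    max_tuple_size: int = 2,
    match_map: MatchMap | None = None,
    alpha: float = 0.8,
) -> list[tuple[tuple[str, ...], int, float]]:
    """Motif tuples jointly present at high frequency within each cluster.

    Returns (motif tuple, cluster_id, joint presence frequency) rows with
    frequency >= min_pair_freq, sorted by descending frequency. When a
    match map is supplied, homotypic composites (the same motif occurring
    at least twice in a peak, which a binary vector cannot encode) are
    detected by placement counting and reported as (motif, motif) tuples.
    """
    B = np.asarray(B)
    index = {pid: i for i, pid in enumerate(peak_ids)}
    col = {mid: j for j, mid in enumerate(motif_ids)}
    out: list[tuple[tuple[str, ...], int, float]] = []
    for cluster in clusters:
        rows = [index[pid] for pid in cluster.peak_ids]
        if not rows:
            continue
        sub = B[rows]
        for size in range(2, max_tuple_size + 1):
            for tup in combinations(motif_ids, size):
                freq = float(np.all(sub[:, [col[m] for m in tup]] == 1, axis=1).mean())
                if freq >= min_pair_freq:
                    out.append((tup, cluster.cluster_id, freq))
        if match_map is not None:
            for mid in motif_ids:
                lom = match_map.loms[mid]
                n_multi = sum(
                    len(match_map.hits(pid, mid, alpha)) >= 2 for pid in cluster.peak_ids
                )
                freq = n_multi / len(cluster.peak_ids)
                if freq >= min_pair_freq:
                    out.append(((mid, mid), cluster.cluster_id, float(freq)))
    return sorted(out, key=lambda r: (-r[2], r[1], r[0]))
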