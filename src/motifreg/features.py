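"""Motif-match features: sliding log-odds scans, shift and normalization.

Every (peak, motif) pair is scored by the best match of the motif's
log-odds matrix slid along the peak sequence (both strands by default).
The raw feature is ``best_match - max_score`` where max_score is the
highest score any sequence could achieve against the matrix, so raw
features are <= 0 with 0 exactly at a perfect-consensus match. Per peak,
the raw vector is shifted by its minimum (making entries nonnegative) and
divided by its Euclidean norm, yielding the unit-norm feature rows the
regression consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from motifreg.io import ALPHABET, MotifModel
from motifreg.prep import PeakSequence

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_PRESENCE_ALPHA = 0.8

Strands = Literal["one", "both"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(ALPHABET + "N"):
    _ENCODE[ord(_a)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to indices A=0, C=1, G=2, T=3, N=4."""
    codes = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains letters outside ACGTN")
    return codes.astype(np.intp)


@dataclass
class LogOddsMatrix:
    """Log-odds scoring matrix (base-2 bits) derived from a PSSM.

    ``max_score`` is the sum over positions of the best letter's score —
    the score of the matrix's consensus, i.e. the maximum achievable by any
    sequence.
    """

    motif_id: str
    lom: np.ndarray
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.lom = np.asarray(self.lom, dtype=float)
        if self.lom.ndim != 2 or self.lom.shape[1] != 4:
            raise ValueError("log-odds matrix must be L x 4")
        self.max_score = float(self.lom.max(axis=1).sum())

    @property
    def length(self) -> int:
        return self.lom.shape[0]

    def reverse_complement(self) -> "LogOddsMatrix":
        # complement = reverse column order ACGT -> TGCA; then reverse positions
        return LogOddsMatrix(motif_id=self.motif_id, lom=self.lom[::-1, ::-1].copy())


@dataclass(frozen=True)
class Match:
    """One motif placement on a peak window (offset on the forward strand)."""

    offset: int
    strand: str  # "+" or "-"
    score: float


def build_log_odds(motif: MotifModel) -> LogOddsMatrix:
    """Pseudocount-regularized base-2 log-odds of a letter-probability matrix.

    lom[p, a] = log2( (probs[p, a] + c) / (1 + 4c) / background[a] ) with
    pseudocount c. With c = 0 a zero probability yields -inf, which is
    permitted: such a placement can never be the best match unless every
    placement is impossible.
    """
    c = motif.pseudocount
    if (motif.background <= 0).any():
        raise ValueError(f"motif {motif.id}: background must be strictly positive")
    with np.errstate(divide="ignore"):
        lom = np.log2((motif.probs + c) / (1.0 + 4.0 * c) / motif.background[np.newaxis, :])
    return LogOddsMatrix(motif_id=motif.id, lom=lom)


def _window_scores(codes: np.ndarray, lom: LogOddsMatrix) -> np.ndarray:
    """Score of every length-L placement along an encoded sequence.

    N bases (code 4) contribute 0 to every placement score.
    """
    scoring = np.hstack([lom.lom, np.zeros((lom.length, 1))])  # column 4 = N
    windows = sliding_window_view(codes, lom.length)  # (n_offsets, L)
    per_pos = scoring[np.arange(lom.length)[np.newaxis, :], windows]
    return per_pos.sum(axis=1)


def best_match_score(
    seq: str, lom: LogOddsMatrix, strands: Strands = "both"
) -> tuple[float, int, str]:
    """Best sliding-window log-odds match of a motif in a sequence.

    Returns (score, offset, strand); offsets are forward-strand positions
    of the placement's left edge. The reverse strand is scanned by scoring
    the reverse-complemented matrix against the forward sequence, which
    leaves offsets in forward coordinates. Ties prefer the forward strand,
    then the smallest offset.
    """
    if len(seq) < lom.length:
        raise ValueError(f"sequence ({len(seq)} bp) shorter than motif {lom.motif_id} "
                         f"({lom.length} bp)")
    codes = encode_sequence(seq)
    fwd = _window_scores(codes, lom)
    best_off = int(np.argmax(fwd))
    best = (float(fwd[best_off]), best_off, "+")
    if strands == "both":
        rev = _window_scores(codes, lom.reverse_complement())
        r_off = int(np.argmax(rev))
        if rev[r_off] > best[0]:
            best = (float(rev[r_off]), r_off, "-")
    return best


def scan_matches(
    seq: str, lom: LogOddsMatrix, min_score: float, strands: Strands = "both"
) -> list[Match]:
    """All placements scoring at least ``min_score``, sorted by offset."""
    codes = encode_sequence(seq)
    hits = [
        Match(int(off), "+", float(s))
        for off, s in enumerate(_window_scores(codes, lom))
        if s >= min_score
    ]
    if strands == "both":
        hits += [
            Match(int(off), "-", float(s))
            for off, s in enumerate(_window_scores(codes, lom.reverse_complement()))
            if s >= min_score
        ]
    return sorted(hits, key=lambda m: (m.offset, m.strand))


@dataclass
class MatchMap:
    """Best motif placements for every (peak, motif) pair.

    Keeps the scanned peaks and log-odds matrices so sub-threshold detail
    (all placements above any score floor) can be enumerated lazily.
    """

    peaks: list[PeakSequence]
    loms: dict[str, LogOddsMatrix]
    strands: Strands
    best: dict[tuple[str, str], Match]

    @property
    def peak_ids(self) -> list[str]:
        return [ps.peak.id for ps in self.peaks]

    @property
    def motif_ids(self) -> list[str]:
        return list(self.loms)

    def hits(self, peak_id: str, motif_id: str, alpha: float) -> list[Match]:
        """All placements with score >= alpha * max_score for the pair."""
        if motif_id not in self.loms:
            raise KeyError(f"motif {motif_id!r} absent from match map")
        lom = self.loms[motif_id]
        by_id = {ps.peak.id: ps for ps in self.peaks}
        return scan_matches(by_id[peak_id].seq, lom, alpha * lom.max_score, self.strands)


def build_match_map(
    peaks: Sequence[PeakSequence],
    motifs: Sequence[MotifModel],
    strands: Strands = "both",
) -> MatchMap:
    loms = {m.id: build_log_odds(m) for m in motifs}
    best: dict[tuple[str, str], Match] = {}
    for ps in peaks:
        for mid, lom in loms.items():
            score, offset, strand = best_match_score(ps.seq, lom, strands)
            best[(ps.peak.id, mid)] = Match(offset, strand, score)
    return MatchMap(peaks=list(peaks), loms=loms, strands=strands, best=best)


@dataclass
class FeatureMatrix:
    """Peaks-by-motifs feature matrix plus the log-score regression target.

    ``raw`` holds best_match - max_score (all entries <= 0); ``V`` holds the
    per-row shifted, unit-Euclidean-norm features; ``y`` the natural log of
    the peak enrichment scores.
    """

    peak_ids: list[str]
    motif_ids: list[str]
    V: np.ndarray
    raw: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.V.shape
        if self.raw.shape != (n, m) or self.y.shape != (n,):
            raise ValueError("inconsistent feature-matrix shapes")
        if len(self.peak_ids) != n or len(self.motif_ids) != m:
            raise ValueError("id lists do not match matrix shape")


def _raw_rows(
    seqs: Sequence[str], loms: Sequence[LogOddsMatrix], strands: Strands
) -> np.ndarray:
    raw = np.empty((len(seqs), len(loms)))
    for j, lom in enumerate(loms):
        for i, seq in enumerate(seqs):
            score, _, _ = best_match_score(seq, lom, strands)
            raw[i, j] = score - lom.max_score
    return raw


def shift_and_normalize(raw: np.ndarray) -> np.ndarray:
    """Per-row shift by the row minimum, then divide by the Euclidean norm."""
    shifted = raw - raw.min(axis=1, keepdims=True)
    norms = np.linalg.norm(shifted, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(
            f"feature row {bad} is all-zero after shifting; at least 2 motifs with "
            "distinct match scores are required"
        )
    return shifted / norms[:, np.newaxis]


def vectorize(
    peaks: Sequence[PeakSequence],
    motifs: Sequence[MotifModel],
    strands: Strands = "both",
    loms: Sequence[LogOddsMatrix] | None = None,
) -> FeatureMatrix:
    """Build the regression design: normalized motif features and log scores.

    ``loms`` overrides the log-odds matrices derived from ``motifs`` (used
    for scans with externally transformed matrices).
    """
    if loms is None:
        loms = [build_log_odds(m) for m in motifs]
    widths = {ps.width for ps in peaks}
    if len(widths) > 1:
        raise ValueError(f"peaks have mixed widths {sorted(widths)}; uniformize first")
    if widths and max(lom.length for lom in loms) > next(iter(widths)):
        raise ValueError("a motif is longer than the peak window")
    for ps in peaks:
        if not ps.peak.score > 0:
            raise ValueError(f"peak {ps.peak.id}: nonpositive score, log target undefined")

    raw = _raw_rows([ps.seq for ps in peaks], loms, strands)
    V = shift_and_normalize(raw)
    y = np.array([math.log(ps.peak.score) for ps in peaks])
    return FeatureMatrix(
        peak_ids=[ps.peak.id for ps in peaks],
        motif_ids=[lom.motif_id for lom in loms],
        V=V,
        raw=raw,
        y=y,
    )


def presence_calls(match_map: MatchMap, alpha: float = DEFAULT_PRESENCE_ALPHA) -> np.ndarray:
    """Binary peaks-by-motifs presence matrix.

    A motif is present in a peak when its best match scores at least
    alpha * max_score. A uniform motif (max_score 0) is present everywhere:
    every placement scores 0 >= alpha * 0.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    pids, mids = match_map.peak_ids, match_map.motif_ids
    B = np.zeros((len(pids), len(mids)), dtype=int)
    for i, pid in enumerate(pids):
        for j, mid in enumerate(mids):
            m = match_map.best[(pid, mid)]
            if m.score >= alpha * match_map.loms[mid].max_score:
                B[i, j] = 1
    return B
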