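"""SNP depletion in motif-mapped positions (hypergeometric test).

True binding sites are expected to carry SNPs less often than surrounding
peak sequence. Motif-match base positions are mapped onto genomic
coordinates, intersected with a SNP set, and the SNP fraction inside
matches is compared with the fraction over all peak-window positions via a
lower-tail hypergeometric test (drawing n motif positions from N window
positions of which K carry SNPs, observing k SNP-carrying positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from scipy.stats import hypergeom

from motifreg.features import MatchMap
from motifreg.io import SnpSet
from motifreg.prep import PeakSequence

DEFAULT_ALPHA = 0.8


@dataclass
class EnrichmentResult:
    """Counts and hypergeometric p-value for SNP depletion in motif positions.

    n motif-mapped base positions of which k carry SNPs, against N total
    peak-window positions of which K carry SNPs. Percentages are reported
    to two decimals, matching the granularity of the counts.
    """

    motif_bp: int  # n
    motif_snp_bp: int  # k
    total_bp: int  # N
    total_snp_bp: int  # K
    motif_pct: float
    total_pct: float
    p_value: float

    @classmethod
    def from_counts(cls, k: int, n: int, K: int, N: int,
                    tail: Literal["lower", "upper"] = "lower") -> "EnrichmentResult":
        _check_counts(k, n, K, N)
        return cls(
            motif_bp=n,
            motif_snp_bp=k,
            total_bp=N,
            total_snp_bp=K,
            motif_pct=round(100.0 * k / n, 2),
            total_pct=round(100.0 * K / N, 2),
            p_value=hypergeom_depletion(k, n, K, N, tail=tail),
        )


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and k <= K <= N and n >= 1):
        raise ValueError(f"invalid count ordering: k={k}, n={n}, K={K}, N={N}")


def hypergeom_depletion(k: int, n: int, K: int, N: int,
                        tail: Literal["lower", "upper"] = "lower") -> float:
    """Hypergeometric tail probability for k SNP hits in n motif positions.

    lower (default, the depletion test): P(X <= k) = sum_{i<=k}
    C(K, i) C(N-K, n-i) / C(N, n); upper: P(X >= k). Computed in log space
    by scipy, stable for N in the millions.
    """
    _check_counts(k, n, K, N)
    if tail == "lower":
        return float(hypergeom.cdf(k, N, K, n))
    if tail == "upper":
        return float(hypergeom.sf(k - 1, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


def motif_positions(
    match_map: MatchMap,
    peaks: Sequence[PeakSequence],
    motif_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> set[tuple[str, int]]:
    """Genomic base positions covered by motif matches scoring >= alpha * max.

    The union over the selected motifs and all peaks; overlapping matches
    contribute each base once (set semantics).
    """
    for mid in motif_ids:
        if mid not in match_map.loms:
            raise KeyError(f"motif {mid!r} absent from match map")
    positions: set[tuple[str, int]] = set()
    for ps in peaks:
        chrom, win_start, _ = ps.window
        for mid in motif_ids:
            length = match_map.loms[mid].length
            for hit in match_map.hits(ps.peak.id, mid, alpha):
                positions.update(
                    (chrom, win_start + hit.offset + p) for p in range(length)
                )
    return positions


def window_positions(peaks: Sequence[PeakSequence]) -> set[tuple[str, int]]:
    """All distinct genomic base positions covered by the peak windows."""
    out: set[tuple[str, int]] = set()
    for ps in peaks:
        chrom, start, end = ps.window
        out.update((chrom, p) for p in range(start, end))
    return out


def enrichment_report(
    positions: set[tuple[str, int]],
    snps: SnpSet,
    peaks: Sequence[PeakSequence],
    count_mode: Literal["distinct", "length"] = "distinct",
    tail: Literal["lower", "upper"] = "lower",
) -> EnrichmentResult:
    """SNP fractions inside motif positions vs. all peak-window positions.

    count_mode selects whether the window total N counts each genomic base
    once across overlapping windows (distinct) or sums window lengths with
    multiplicity (length; K then also counts a SNP once per covering
    window).
    """
    if not positions:
        raise ValueError("empty motif-position set")
    k = len(positions & snps.positions)
    n = len(positions)
    if count_mode == "distinct":
        windows = window_positions(peaks)
        N = len(windows)
        K = len(windows & snps.positions)
    elif count_mode == "length":
        N = sum(ps.width for ps in peaks)
        K = sum(
            1
            for ps in peaks
            for p in range(ps.window[1], ps.window[2])
            if (ps.window[0], p) in snps.positions
        )
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    return EnrichmentResult.from_counts(k=k, n=n, K=K, N=N, tail=tail)
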