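"""Peak preparation: fixed-width windows, filtering, score-sorted clustering.

Peak callers emit intervals of wildly varying length (1 bp to several kb).
Downstream motif scoring wants a uniform window, so every peak is
uniformized to exactly W bp (default 200), either around a caller-supplied
summit (center mode) or by symmetric enlargement/trimming of the called
interval (interval mode). Score-sorted peaks are then grouped into
fixed-size clusters so an external motif-discovery run (e.g. MEME in ZOOPS
mode) can be parallelized over narrow score ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

from motifreg.io import PeakRecord, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 200
DEFAULT_GROUP_SIZE = 200
DEFAULT_QMAX = 0.05
DEFAULT_PROMOTER_FLANK = 2000


@dataclass
class PeakSequence:
    """A peak with its uniformized W-bp sequence and the window extracted."""

    peak: PeakRecord
    seq: str
    window: tuple[str, int, int]

    def __post_init__(self) -> None:
        chrom, start, end = self.window
        if len(self.seq) != end - start:
            raise ValueError(f"peak {self.peak.id}: sequence length != window length")

    @property
    def width(self) -> int:
        return len(self.seq)


@dataclass
class PeakCluster:
    """Consecutive-score peak group (ascending), input unit for motif discovery."""

    rank: int
    peaks: list[PeakSequence]

    @property
    def size(self) -> int:
        return len(self.peaks)


def uniformize(
    peak: PeakRecord,
    genome: Mapping[str, str],
    width: int = DEFAULT_WIDTH,
    mode: Literal["center", "interval"] = "interval",
) -> PeakSequence:
    """Extract an exactly ``width``-bp window for a peak.

    center mode: the window is [center - W/2, center + W/2) around the
    caller-supplied summit. interval mode: the called interval is enlarged
    or trimmed symmetrically to exactly W bp, with the odd leftover base
    going to the right side. Windows running past a chromosome boundary are
    shifted inward (with a warning) so the emitted sequence is always W bp.
    """
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} absent from genome")
    chrom_seq = genome[peak.chrom]
    clen = len(chrom_seq)
    if clen < width:
        raise ValueError(f"chromosome {peak.chrom} shorter ({clen}) than window width {width}")

    if mode == "center":
        if peak.center is None:
            raise ValueError(f"peak {peak.id}: center mode requires a peak center")
        start = peak.center - width // 2
    elif mode == "interval":
        delta = width - (peak.end - peak.start)
        # symmetric change; the odd leftover base always lands on the right
        left = delta // 2 if delta >= 0 else -((-delta) // 2)
        start = peak.start - left
    else:
        raise ValueError(f"unknown uniformization mode {mode!r}")
    end = start + width

    if start < 0 or end > clen:
        shifted = min(max(start, 0), clen - width)
        logger.warning(
            "peak %s: window (%d, %d) extends past chromosome %s [0, %d); shifted to (%d, %d)",
            peak.id, start, end, peak.chrom, clen, shifted, shifted + width,
        )
        start = shifted
        end = start + width

    return PeakSequence(peak=peak, seq=chrom_seq[start:end], window=(peak.chrom, start, end))


def filter_peaks(
    peaks: Sequence[PeakRecord],
    mode: Literal["none", "qvalue", "promoter"] = "none",
    qmax: float = DEFAULT_QMAX,
    tss: Sequence[tuple[str, int, int]] | None = None,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> list[PeakRecord]:
    """Apply one of the three peak-filtering modes.

    none: identity. qvalue: keep peaks with qvalue <= qmax (every peak must
    carry one). promoter: keep peaks whose interval overlaps any TSS
    interval expanded by ``promoter_flank`` on both sides.
    """
    if mode == "none":
        return list(peaks)
    if mode == "qvalue":
        missing = [p.id for p in peaks if p.qvalue is None]
        if missing:
            raise ValueError(f"qvalue filter: peaks without a qvalue: {', '.join(missing)}")
        return [p for p in peaks if p.qvalue <= qmax]
    if mode == "promoter":
        if not tss:
            raise ValueError("promoter filter requires a non-empty TSS interval list")
        kept = []
        for p in peaks:
            for chrom, t_start, t_end in tss:
                if chrom != p.chrom:
                    continue
                lo, hi = t_start - promoter_flank, t_end + promoter_flank
                if p.start < hi and p.end > lo:
                    kept.append(p)
                    break
        return kept
    raise ValueError(f"unknown filter mode {mode!r}")


def cluster_by_score(
    peaks: Sequence[PeakSequence], group_size: int = DEFAULT_GROUP_SIZE
) -> list[PeakCluster]:
    """Sort peaks by ascending score and chunk into consecutive groups.

    Each cluster holds ``group_size`` consecutive-score peaks; a trailing
    remainder of fewer than group_size/2 peaks is merged into the previous
    cluster (a tiny cluster is a degenerate motif-discovery input). Score
    ties are broken by peak id for determinism.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda ps: (ps.peak.score, ps.peak.id))
    chunks = [list(ordered[i : i + group_size]) for i in range(0, len(ordered), group_size)]
    if len(chunks) > 1 and len(chunks[-1]) < group_size / 2:
        chunks[-2].extend(chunks.pop())
    return [PeakCluster(rank=i, peaks=chunk) for i, chunk in enumerate(chunks)]


def export_cluster_fastas(clusters: Sequence[PeakCluster], outdir: str | Path) -> list[Path]:
    """Write one FASTA per cluster plus a rank -> path manifest.

    These files are the per-cluster inputs handed to an external
    motif-discovery tool; record ids are the peak ids.
    """
    if not clusters:
        raise ValueError("no clusters to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cluster in clusters:
        path = outdir / f"cluster_{cluster.rank:04d}.fasta"
        write_fasta({ps.peak.id: ps.seq for ps in cluster.peaks}, path)
        paths.append(path)
    with open(outdir / "clusters.manifest.tsv", "w") as fh:
        fh.write("rank\tn_peaks\tpath\n")
        for cluster, path in zip(clusters, paths):
            fh.write(f"{cluster.rank}\t{cluster.size}\t{path.name}\n")
    return paths
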