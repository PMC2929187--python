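"""Synthetic ChIP-Seq fixtures with known ground truth.

Generates background DNA, plants instances of a few "true" motifs at a
controlled per-peak probability, and draws peak enrichment scores from the
same linear model the pipeline fits: log score = b + sum_j w_j x_ij +
Gaussian noise, where x_ij are the pipeline's own normalized motif
features recomputed on the generated sequences. SNPs are dropped uniformly
at a configurable rate, optionally thinned inside planted-motif footprints
to emulate selective constraint at true binding sites. Every stage of the
pipeline is therefore testable against recorded ground truth without any
external download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from motifreg import io
from motifreg.features import build_log_odds, shift_and_normalize, _raw_rows
from motifreg.io import MotifModel, PeakRecord, SnpSet
from motifreg.prep import PeakSequence
from motifreg.regression import MotifRanking

CHROM = "chrS"


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the pipeline's intended regime scaled to desk size:
    500 peaks of 200 bp against 50 motif candidates, of which five are
    planted with mixed strengthening/weakening weights (+3, +2, +1, -1,
    -2). Planted motifs occur in half the peaks (``plant_prob``), roughly
    the occurrence rate of a primary motif among its factor's peaks. Noise
    sigma 0.1 on the log score; SNPs at 0.5% of positions.
    """

    n_peaks: int = 500
    width: int = 200
    n_motifs: int = 50
    motif_length: int = 8
    planted_weights: dict[int, float] = field(
        default_factory=lambda: {0: 3.0, 1: 2.0, 2: 1.0, 3: -1.0, 4: -2.0}
    )
    plant_prob: float = 0.5
    noise_sigma: float = 0.1
    snp_rate: float = 0.005
    snp_depletion: float = 1.0  # multiplier on snp_rate inside motif footprints
    intercept: float = 3.0
    consensus_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.plant_prob <= 1:
            raise ValueError("plant_prob must be in [0, 1]")
        if not 0 <= self.snp_rate <= 1:
            raise ValueError("snp_rate must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.motif_length > self.width:
            raise ValueError("motif longer than the peak window")
        if any(j >= self.n_motifs for j in self.planted_weights):
            raise ValueError("planted motif index out of range")


@dataclass
class SyntheticData:
    """One generated dataset plus its ground truth."""

    spec: SyntheticSpec
    genome: dict[str, str]
    peaks: list[PeakRecord]
    peak_seqs: list[PeakSequence]
    motifs: list[MotifModel]
    snps: SnpSet
    truth: dict


def _random_motifs(spec: SyntheticSpec, rng: np.random.Generator) -> list[MotifModel]:
    # per-position consensus probabilities vary around consensus_prob so
    # motifs have heterogeneous information content, as discovered motifs
    # do; identical column profiles would make distinct motifs tie on
    # best-match scores, collapsing whole feature rows
    motifs = []
    for j in range(spec.n_motifs):
        consensus = rng.integers(0, 4, size=spec.motif_length)
        p = np.clip(
            spec.consensus_prob + rng.uniform(-0.1, 0.1, size=spec.motif_length),
            0.3, 0.99,
        )
        probs = np.repeat(((1.0 - p) / 3.0)[:, np.newaxis], 4, axis=1)
        probs[np.arange(spec.motif_length), consensus] = p
        motifs.append(MotifModel(id=f"m{j:03d}", probs=probs, source="synthetic"))
    return motifs


def _sample_instance(motif: MotifModel, rng: np.random.Generator) -> str:
    letters = [rng.choice(4, p=row) for row in motif.probs]
    return "".join(io.ALPHABET[a] for a in letters)


def generate(spec: SyntheticSpec, outdir: str | Path | None = None) -> SyntheticData:
    """Generate a dataset; optionally write the five pipeline input files.

    Files written (when ``outdir`` is given): genome.fasta, peaks.tsv,
    motifs.meme, snps.bed, truth.json. Identical specs (including seed)
    produce byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = _random_motifs(spec, rng)

    chrom_len = spec.n_peaks * spec.width
    seq = rng.integers(0, 4, size=chrom_len)

    plants = []
    footprint = np.zeros(chrom_len, dtype=bool)
    for i in range(spec.n_peaks):
        win_start = i * spec.width
        for j, _w in spec.planted_weights.items():
            if rng.random() >= spec.plant_prob:
                continue
            motif = motifs[j]
            offset = int(rng.integers(0, spec.width - motif.length + 1))
            inst = _sample_instance(motif, rng)
            pos = win_start + offset
            seq[pos : pos + motif.length] = [io.ALPHABET.index(a) for a in inst]
            footprint[pos : pos + motif.length] = True
            plants.append({"peak_index": i, "motif": motif.id, "offset": offset})

    genome_seq = "".join(io.ALPHABET[a] for a in seq)
    genome = {CHROM: genome_seq}

    # features on the generated sequences, with the pipeline's own scanner
    seqs = [genome_seq[i * spec.width : (i + 1) * spec.width] for i in range(spec.n_peaks)]
    loms = [build_log_odds(m) for m in motifs]
    raw = _raw_rows(seqs, loms, strands="both")
    V = shift_and_normalize(raw)

    w = np.zeros(spec.n_motifs)
    for j, wj in spec.planted_weights.items():
        w[j] = wj
    log_scores = spec.intercept + V @ w + rng.normal(0.0, spec.noise_sigma, spec.n_peaks)
    scores = np.exp(log_scores)

    peaks, peak_seqs = [], []
    for i in range(spec.n_peaks):
        start, end = i * spec.width, (i + 1) * spec.width
        rec = PeakRecord(chrom=CHROM, start=start, end=end, score=float(scores[i]),
                         qvalue=None, center=start + spec.width // 2)
        peaks.append(rec)
        peak_seqs.append(PeakSequence(peak=rec, seq=seqs[i], window=(CHROM, start, end)))

    # SNPs: uniform rate, thinned inside planted footprints by the depletion factor
    u = rng.random(chrom_len)
    rate = np.where(footprint, spec.snp_rate * spec.snp_depletion, spec.snp_rate)
    snp_pos = np.flatnonzero(u < rate)
    snps = SnpSet(frozenset((CHROM, int(p)) for p in snp_pos))

    truth = {
        "seed": spec.seed,
        "motif_ids": [m.id for m in motifs],
        "weights": {motifs[j].id: wj for j, wj in sorted(spec.planted_weights.items())},
        "intercept": spec.intercept,
        "plants": plants,
        "n_snps": int(len(snp_pos)),
        "spec": asdict(spec),
    }
    data = SyntheticData(spec=spec, genome=genome, peaks=peaks, peak_seqs=peak_seqs,
                         motifs=motifs, snps=snps, truth=truth)
    if outdir is not None:
        _write_dataset(data, Path(outdir))
    return data


def _write_dataset(data: SyntheticData, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(data.genome, outdir / "genome.fasta")
    io.write_peak_table(data.peaks, outdir / "peaks.tsv")
    io.write_meme_motifs(data.motifs, outdir / "motifs.meme")
    io.write_bed(
        sorted((c, p, p + 1) for c, p in data.snps.positions), outdir / "snps.bed"
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def truth_check(truth: Mapping, ranking: MotifRanking) -> dict[str, float]:
    """Recovery metrics of a fitted ranking against recorded ground truth.

    sign_accuracy: fraction of planted motifs whose fitted coefficient sign
    matches the planted weight sign (absent/zero counts as wrong).
    top_k_overlap: overlap of the ranking's top-k (k = number planted) with
    the planted set. rank_correlation: Spearman correlation between planted
    |weights| and fitted |coefficients| over the planted motifs.
    """
    weights: dict[str, float] = dict(truth["weights"])
    if not weights:
        raise ValueError("ground truth contains no planted weights")
    fitted = {mid: coef for mid, coef, _ in ranking.rows}
    truth_ids = set(weights)
    known = set(truth.get("motif_ids", truth_ids))
    unknown = set(fitted) - known
    if unknown:
        raise ValueError(f"ranking contains motif ids absent from the ground truth: "
                         f"{', '.join(sorted(unknown))}")

    k = len(weights)
    signs_ok = sum(
        1 for mid, w in weights.items() if np.sign(fitted.get(mid, 0.0)) == np.sign(w)
    )
    top_k = set(ranking.motif_ids[:k])
    overlap = len(top_k & truth_ids) / k
    truth_mag = [abs(weights[mid]) for mid in sorted(weights)]
    fit_mag = [abs(fitted.get(mid, 0.0)) for mid in sorted(weights)]
    rho = stats.spearmanr(truth_mag, fit_mag).statistic if k > 1 else float("nan")
    return {
        "sign_accuracy": signs_ok / k,
        "top_k_overlap": overlap,
        "rank_correlation": float(rho),
    }
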