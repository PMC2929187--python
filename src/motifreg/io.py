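"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (peak/genome sequences), tab-separated peak tables with a
configurable column map, MEME minimal motif format v4, BED3 (SNPs, TSS),
and the pipeline's own tab-separated matrix outputs.

Internal coordinates are always 0-based half-open (BED convention); the
peak-table dialect declares whether the input file is 1-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_DNA_OK = set("ACGTN")


class FormatError(ValueError):
    """A malformed record or file in one of the supported formats."""


@dataclass
class PeakRecord:
    """One called ChIP-Seq peak with its enrichment score and metadata.

    Coordinates are 0-based half-open. ``score`` is a positive enrichment
    statistic (PeakSeq-style); its natural log is the regression target.
    ``qvalue`` is the multiple-testing-adjusted peak significance against a
    control sample; ``center`` is a read-density summit when the caller
    provides one.
    """

    chrom: str
    start: int
    end: int
    score: float
    qvalue: float | None = None
    center: int | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not self.score > 0:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: score must be > 0")
        if self.qvalue is not None and not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: qvalue outside [0, 1]")
        if self.center is not None and not self.start <= self.center < self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: center {self.center} outside interval"
            )
        if self.id is None:
            self.id = f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class MotifModel:
    """A PSSM: per-position letter probabilities over ACGT plus a background.

    ``probs`` has shape (L, 4) with rows summing to 1; ``background`` is the
    genomic letter composition the log-odds are taken against.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    source: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"motif {self.id}: probability matrix must be L x 4 with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError(f"motif {self.id}: probability rows do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise FormatError(f"motif {self.id}: background does not sum to 1")
        if self.pseudocount < 0:
            raise ValueError(f"motif {self.id}: pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class SnpSet:
    """A set of single-nucleotide polymorphism positions, (chrom, 0-based pos)."""

    positions: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions:
            if pos < 0:
                raise ValueError(f"negative SNP position {chrom}:{pos}")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_bed(cls, intervals: Iterable[tuple[str, int, int]]) -> "SnpSet":
        """Expand BED intervals to per-base positions (SNP BEDs are 1 bp wide)."""
        pos = set()
        for chrom, start, end in intervals:
            for p in range(start, end):
                pos.add((chrom, p))
        return cls(frozenset(pos))


@dataclass
class PeakTableDialect:
    """Column mapping for a tab-separated peak table.

    ``columns`` maps the canonical field names (chrom, start, end, score and
    optionally qvalue, center) to the column names of the file.
    ``one_based`` declares that start/center in the file are 1-based
    inclusive and must be shifted to the internal 0-based half-open system.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "chrom": "chrom",
            "start": "start",
            "end": "end",
            "score": "score",
        }
    )
    one_based: bool = False

    MANDATORY = ("chrom", "start", "end", "score")


def read_peak_table(path: str | Path, dialect: PeakTableDialect | None = None) -> list[PeakRecord]:
    """Read a tab-separated peak table into PeakRecords.

    Rows with a nonpositive score are dropped (the log-score regression
    target is undefined for them); the drop count is logged. Raises
    :class:`FormatError` for a missing mandatory column and ValueError with
    the row number for an unparseable numeric cell.
    """
    dialect = dialect or PeakTableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for fld in PeakTableDialect.MANDATORY:
        col = dialect.columns.get(fld)
        if col is None or col not in df.columns:
            raise FormatError(f"peak table {path}: missing mandatory column {fld!r} ({col!r})")

    records: list[PeakRecord] = []
    n_dropped = 0
    shift = 1 if dialect.one_based else 0
    for i, row in df.iterrows():
        def cell(fld: str) -> str | None:
            col = dialect.columns.get(fld)
            if col is None or col not in df.columns:
                return None
            val = row[col]
            return None if pd.isna(val) else val

        try:
            start = int(cell("start")) - shift
            end = int(cell("end"))
            score = float(cell("score"))
            qvalue = cell("qvalue")
            center = cell("center")
            qvalue = float(qvalue) if qvalue is not None else None
            center = int(center) - shift if center is not None else None
        except (TypeError, ValueError) as exc:
            raise ValueError(f"peak table {path}: unparseable numeric cell in row {i + 2}: {exc}")
        if score <= 0:
            n_dropped += 1
            continue
        records.append(
            PeakRecord(chrom=cell("chrom"), start=start, end=end, score=score,
                       qvalue=qvalue, center=center)
        )
    if n_dropped:
        logger.warning("read_peak_table(%s): dropped %d rows with nonpositive score",
                       path, n_dropped)
    return records


def write_peak_table(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    rows = []
    for p in peaks:
        rows.append({"chrom": p.chrom, "start": p.start, "end": p.end, "score": p.score,
                     "qvalue": p.qvalue, "center": p.center, "id": p.id})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_MATRIX_HEADER = re.compile(r"^letter-probability matrix:")


def _validate_meme_rows(path: str | Path) -> None:
    # Biopython renormalizes probability rows silently; enforce the format
    # contract (each row sums to ~1) on the raw text before parsing.
    in_matrix = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if _MATRIX_HEADER.match(stripped):
                in_matrix = True
                continue
            if in_matrix:
                fields = stripped.split()
                if len(fields) == 4:
                    try:
                        total = sum(float(x) for x in fields)
                    except ValueError:
                        in_matrix = False
                        continue
                    if abs(total - 1.0) > 1e-4:
                        raise FormatError(
                            f"{path}:{lineno}: letter-probability row sums to {total:.4f}, not 1"
                        )
                else:
                    in_matrix = False


def read_meme_motifs(path: str | Path) -> list[MotifModel]:
    """Parse a MEME minimal motif file into MotifModels.

    The file-level background frequencies are attached to every motif;
    files without a background line get the uniform 0.25 default.
    """
    _validate_meme_rows(path)
    text = Path(path).read_text()
    if "Background letter frequencies" not in text:
        # the minimal-format parser requires a background block; absent one,
        # the documented default is the uniform composition
        lines = text.splitlines()
        first_motif = next((i for i, ln in enumerate(lines) if ln.startswith("MOTIF")),
                           len(lines))
        lines[first_motif:first_motif] = [
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
        ]
        text = "\n".join(lines) + "\n"
    try:
        parsed = bio_motifs.parse(StringIO(text), "minimal")
    except ValueError as exc:
        raise FormatError(f"{path}: not a valid MEME minimal motif file: {exc}")
    if len(parsed) == 0:
        raise FormatError(f"{path}: no MOTIF blocks found")
    out = []
    for m in parsed:
        bg = np.array([m.background.get(a, 0.25) for a in ALPHABET]) if m.background else np.full(4, 0.25)
        probs = np.array([[m.pwm[a][i] for a in ALPHABET] for i in range(m.length)])
        out.append(MotifModel(id=m.name, probs=probs, background=bg, source=str(path)))
    return out


def write_meme_motifs(motifs: Sequence[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format v4 (lossless to 1e-6 round-trip)."""
    if not motifs:
        raise ValueError("no motifs to write")
    bg = motifs[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {bg[i]:.6f}" for i, a in enumerate(ALPHABET)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> uppercase-sequence mapping.

    Letters outside {A, C, G, T, N} (after case folding) are rejected with
    the offending record ids listed.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    bad: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if set(s) - _DNA_OK:
            bad.append(rec.id)
        seqs[rec.id] = s
    if bad:
        raise FormatError(f"{path}: non-DNA letters in records: {', '.join(bad)}")
    if not seqs:
        raise FormatError(f"{path}: empty FASTA")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (chrom, 0-based start, exclusive end)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                out.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates")
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_matrix(matrix: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str],
                 path: str | Path) -> None:
    """Write a matrix as TSV with a header row and a leading id column."""
    pd.DataFrame(np.asarray(matrix), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", index_label="id", float_format="%.17g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
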