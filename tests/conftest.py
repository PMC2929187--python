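import numpy as np
import pytest

from motifreg.io import MotifModel, PeakRecord
from motifreg.prep import PeakSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_motif(mid: str, consensus: str, p: float = 1.0, background=None,
               pseudocount: float = 0.0) -> MotifModel:
    """A PSSM with probability ``p`` on each consensus letter, rest uniform."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    eps = (1.0 - p) / 3.0
    probs = np.full((len(consensus), 4), eps)
    for i, a in enumerate(consensus):
        probs[i, idx[a]] = p
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return MotifModel(id=mid, probs=probs, background=bg, pseudocount=pseudocount)


def make_peak_seq(seq: str, score: float = 10.0, chrom: str = "chr1",
                  start: int = 0, pid: str | None = None) -> PeakSequence:
    rec = PeakRecord(chrom=chrom, start=start, end=start + len(seq), score=score, id=pid)
    return PeakSequence(peak=rec, seq=seq, window=(chrom, start, start + len(seq)))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
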