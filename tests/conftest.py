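import numpy as np
import pytest

from isoscape.io_core import TranscriptModel
from isoscape.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def truth_default():
    """Full-default benchmark truth used by the planted-recovery tests."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def truth_small():
    """Smaller, fast benchmark for structural checks."""
    return simulate(SimConfig(seed=7, n_genes=40, read_depth=400))


def random_transcript(rng: np.random.Generator, chrom="chr1", strand=None,
                      max_exons=6, start=None, tid="t") -> TranscriptModel:
    """A random multi- or mono-exon transcript model."""
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 500)) if start is None else start
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 150))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return TranscriptModel(tid, "g", chrom, strand, tuple(exons))
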