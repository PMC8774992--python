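import numpy as np
import pytest

from motifmk.annotation import GeneModel
from motifmk.genome import GenomeSequence
from motifmk.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """A compact genome: one autosome, an X, and a chrU scaffold."""
    return SimConfig(
        seed=11,
        chrom_specs=(
            ("chr2L", 60_000, "autosome"),
            ("chrX", 40_000, "X"),
            ("chrU", 10_000, "unassembled"),
        ),
        n_motifs=60,
        n_genes=30,
    )


@pytest.fixture
def random_genome(rng):
    def make(length=10_000, chrom="chr2L", gc=0.5, n_run=None):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if n_run is not None:
            start, width = n_run
            seq = seq[:start] + "N" * width + seq[start + width:]
        return GenomeSequence({chrom: seq})

    return make


@pytest.fixture
def simple_genes():
    return [
        GeneModel("gA", "chr2L", 2000, 3000, "+", ((2000, 2400), (2600, 3000))),
        GeneModel("gB", "chr2L", 6000, 7000, "-", ((6000, 7000),)),
        GeneModel("gX", "chrX", 1000, 2000, "+", ((1000, 2000),)),
    ]
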