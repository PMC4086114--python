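import numpy as np
import pytest

from rbpscan import build_background
from rbpscan.synth import background_corpus, default_motif, toy_gene_model


@pytest.fixture(scope="session")
def motif():
    return default_motif()


@pytest.fixture(scope="session")
def mid_bg(motif):
    """Mid-intron/intergenic background calibrated on the default corpus."""
    seqs = background_corpus("mid_intron_intergenic", n=1000, length=250, seed=1)
    return build_background(motif, seqs, "mid_intron_intergenic")


@pytest.fixture(scope="session")
def gene_model():
    return toy_gene_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
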