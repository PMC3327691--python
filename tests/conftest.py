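import numpy as np
import pytest

from cnvpower import make_locus_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def deletion_locus():
    """HWE deletion-only locus, variant allele frequency 0.1."""
    return make_locus_model("deletion", 0.1)


@pytest.fixture
def duplication_locus():
    return make_locus_model("duplication", 0.1)


@pytest.fixture
def multiallelic_locus():
    """HWE locus segregating deletion and duplication alleles, each at 0.1."""
    return make_locus_model("multiallelic", 0.1, 0.1)
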