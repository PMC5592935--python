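import numpy as np
import pytest

from gpascent import GenomeSpec, place_qtl, simulate_dh_genotypes
from gpascent.config import default_factors


@pytest.fixture
def small_pop():
    """200 DH lines, 10 chromosomes x 10 markers, 10 evenly spaced QTL."""
    pop = simulate_dh_genotypes(GenomeSpec(n_markers=100), n=200, seed=7)
    return place_qtl(pop, 10)


@pytest.fixture
def study_factors():
    """The five-factor initial region (natural units) as a name->Factor map."""
    return {f.name: f.to_factor() for f in default_factors()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
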