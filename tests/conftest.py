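import logging

import numpy as np
import pytest

from hapfeatures.io_formats import GeneticMap, HaplotypePanel

logging.getLogger("hapfeatures").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_517)


@pytest.fixture()
def uniform_map():
    """1 cM/Mb over 10 Mb."""
    return GeneticMap.uniform(1.0, 10_000_000)


def random_panel(rng, n_hap=10, m=400, length_bp=10_000_000, p_derived=0.5):
    """A panel of mutually random haplotypes (pairwise difference ~ 2p(1-p))."""
    alleles = (rng.random((n_hap, m)) < p_derived).astype(np.uint8)
    positions = np.sort(
        rng.choice(np.arange(1, length_bp), size=m, replace=False)
    )
    return HaplotypePanel(alleles, positions)


@pytest.fixture()
def make_random_panel(rng):
    def _make(**kwargs):
        return random_panel(rng, **kwargs)

    return _make
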