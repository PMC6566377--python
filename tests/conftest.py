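import io

import pytest

from ogclust import SimConfig, make_obo, make_species_panel, parse_obo, sample_families


@pytest.fixture(scope="session")
def default_taxonomy():
    """The 14-species panel: 2 Chl, 2 KCM, 5 ZCC, 5 Emb."""
    return make_species_panel(SimConfig())


@pytest.fixture(scope="session")
def deep_dag():
    """Single-namespace full binary tree of depth 6 (63 terms, 32 at level 6)."""
    return parse_obo(io.StringIO(make_obo(6, 2)))


@pytest.fixture(scope="session")
def small_truth(default_taxonomy):
    """20-family ground truth at default mixture, fixed seed."""
    return sample_families(default_taxonomy, SimConfig(n_families=20, seed=11))
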