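import numpy as np
import pytest

from plastobarcode.synthetic_data import SimulationConfig, make_paper_like_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default 55-sample / 20-species panel shared across tests."""
    return make_paper_like_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_panel():
    """A light panel (10 species x 2, four short loci) for structural checks."""
    cfg = SimulationConfig(
        n_species=10,
        n_individuals=20,
        individuals_min=2,
        individuals_max=2,
        locus_lengths={"P": 800, "F": 800, "R": 600, "Y": 900},
        hotspots=[("P", 200, 500, 8.0)],
        background_pi=0.003,
        intraspecific_depth=0.0002,
        seed=11,
    )
    return make_paper_like_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
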