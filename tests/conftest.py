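import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sugarcg as sc
from sugarcg.synthetic_fixtures import GeneratorSpec, gen_pseudo_aa_traj

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trehalose_graph():
    return sc.build_atom_graph(sc.parse_glycam_name("1GA_0GA"))


@pytest.fixture(scope="session")
def maltose_graph():
    return sc.build_atom_graph(sc.parse_glycam_name("4GB_0GA"))


@pytest.fixture(scope="session")
def all_40_specs():
    return sc.enumerate_disaccharides(["GLC", "MAN"])


@pytest.fixture(scope="session")
def trehalose_fixture():
    """Medium-sized synthetic trehalose trajectory shared across tests."""
    gspec = GeneratorSpec(spec="1GA_0GA", n_frames=20000, seed=3)
    return gspec, gen_pseudo_aa_traj(gspec)


@pytest.fixture(scope="session")
def trehalose_samples(trehalose_fixture):
    _, fx = trehalose_fixture
    return sc.measure_terms(fx.traj, fx.mapping, fx.connectivity, fx.graph)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
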