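import numpy as np
import pytest

import amyloop as al


@pytest.fixture(scope="session")
def closed_params():
    return al.preset("closed")[0]


@pytest.fixture(scope="session")
def mild_params():
    return al.mild_oscillation_parameters()


@pytest.fixture(scope="session")
def mild_tc(mild_params):
    """Mild-oscillation reference run: 1e5 s at 1 s sampling."""
    return al.simulate(
        mild_params, al.SystemState(), 1e5, sampling=al.UniformSampling(dt=1.0)
    )


@pytest.fixture(scope="session")
def ladder_scan():
    """Closed-system aggregation scan over the full 13-point ladder."""
    return al.closed_ladder_scan()


@pytest.fixture(scope="session")
def kinfl_sweep():
    """Coarse k_infl bifurcation sweep at steep=50, infl_ref=0.005."""
    base = al.preset("open_coupled")[0].set("infl_ref", 0.005)
    spec = al.SweepSpec("k_infl", al.grid_values(1e-4, 6e-3, 10), base)
    return al.sweep_1d(spec)


@pytest.fixture(scope="session")
def kplus_sweep(mild_params):
    """Coarse generation-rate sweep over the oscillatory band."""
    spec = al.SweepSpec(
        "k_plus.c0",
        al.grid_values(2e-10, 6e-9, 10),
        mild_params,
        linked=[al.LINK_KPLUS_INF_ZERO],
    )
    return al.sweep_1d(spec)


@pytest.fixture(scope="session")
def gamma_o_sweep(mild_params):
    """Coarse oligomer-clearance attenuation sweep at the mild baseline."""
    spec = al.SweepSpec(
        "gamma_o", al.grid_values(0.01, 1.0, 12, "log"), mild_params
    )
    return al.sweep_1d(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240730)
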