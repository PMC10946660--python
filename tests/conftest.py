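import numpy as np
import pytest

from luxqs import reference_params
from luxqs.dynamics import DEFAULT_CONFIG, default_initial_state, simulate
from luxqs.synth import apply_scenario, generate_clean, make_scenario


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def rich_scenario():
    return make_scenario("rich")


@pytest.fixture(scope="session")
def poor_scenario():
    return make_scenario("poor")


def _preset_traj(name):
    scenario = make_scenario(name)
    p = apply_scenario(reference_params(), scenario)
    return simulate(
        p, DEFAULT_CONFIG, init=default_initial_state(p, scenario), t_grid=scenario.t_grid
    ), p, scenario


@pytest.fixture(scope="session")
def rich_traj():
    """Full-model trajectory of the rich preset with reference parameters."""
    traj, p, scenario = _preset_traj("rich")
    return traj


@pytest.fixture(scope="session")
def poor_traj():
    traj, p, scenario = _preset_traj("poor")
    return traj


@pytest.fixture(scope="session")
def rich_clean(rich_scenario, ref_params):
    """Noise-free rich-preset observation table."""
    return generate_clean(rich_scenario, ref_params)


@pytest.fixture(scope="session")
def coarse_rich_scenario(rich_scenario):
    """Rich preset on an hourly grid — cheap enough for fitting tests."""
    return rich_scenario.replace(t_grid=np.arange(0.0, 16.0 + 1e-9, 1.0))
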