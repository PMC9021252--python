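import numpy as np
import pytest

from nbdgkin import (
    CellGeometry,
    ExperimentDesign,
    KineticParams,
    NoiseSpec,
    default_population,
    make_external_profile,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def step_design():
    return ExperimentDesign(rise_time=0.0, fall_time=0.0)


@pytest.fixture(scope="session")
def profile(design):
    return make_external_profile(design)


@pytest.fixture(scope="session")
def step_profile(step_design):
    return make_external_profile(step_design)


@pytest.fixture(scope="session")
def typical_params():
    """A cell in the slower population component: steady state ~700 a.u.,
    accumulation time constant 1/d = 200 s."""
    return KineticParams(u_gluc=0.26, d_gluc=5e-3)


@pytest.fixture(scope="session")
def typical_geometry():
    return CellGeometry(width=1.0, length=3.0)


@pytest.fixture(scope="session")
def small_experiment(design):
    """12 noisy traces with ground truth, shared across inference tests."""
    traces, prof, params = simulate_experiment(
        default_population(), design, NoiseSpec(), n_cells=12, seed=42
    )
    truth = np.array([p.log for p in params])
    return traces, prof, truth
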