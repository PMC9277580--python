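import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import milestonekit as mk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def flat_potential():
    return mk.FlatPotential()


@pytest.fixture
def linear_chain():
    """Milestones every 1 Å on [0, 4]: 5 milestones, 4 cells."""
    return mk.build_linear_model([0.0, 1.0, 2.0, 3.0, 4.0])


@pytest.fixture
def overdamped_params():
    return mk.DynamicsParams(
        timestep_ps=1e-4, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
    )


@pytest.fixture
def hand_trace_log():
    """The worked single-cell example: collisions (m1, 2), (m2, 5), (m1, 9)."""
    return mk.CollisionLog(
        cell_id=0,
        milestones=np.array([1, 2, 1], dtype=np.int32),
        times_ps=np.array([2.0, 5.0, 9.0]),
        total_time_ps=10.0,
    )


@pytest.fixture(scope="session")
def flat_mmvt_logs():
    """Long flat-potential MMVT run shared by the pipeline-level checks.

    Milestones at 0..4 Å, D = 1 Å²/ps, 4000 ps per cell at a 2e-5 ps
    timestep: several million collisions in total, enough for the
    Smoluchowski MFPT oracle at the percent level.
    """
    model = mk.build_linear_model([0.0, 1.0, 2.0, 3.0, 4.0])
    params = mk.DynamicsParams(
        timestep_ps=2e-5, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
    )
    pot = mk.FlatPotential()
    logs = [
        mk.mmvt_run(model, c, pot, params, duration_ps=4000.0, seed=1000 + c)
        for c in range(model.n_cells)
    ]
    return model, params, logs


@pytest.fixture(scope="session")
def flat_mmvt_fit(flat_mmvt_logs):
    model, params, logs = flat_mmvt_logs
    return model, params, logs, mk.MMVTMilestoningModel(logs, model).fit()
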