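import numpy as np
import pytest

from qqcr import ParameterSet, SolverSettings, Trajectory, baseline


@pytest.fixture
def p() -> ParameterSet:
    return baseline()


@pytest.fixture
def fast_solver() -> SolverSettings:
    """Looser tolerances for tests where speed matters more than 1e-8 accuracy."""
    return SolverSettings(rtol=1e-7, atol=1e-9)


def synthetic_trajectory(t, X, u=0.5, Q_X=None):
    """Build a Trajectory from closed-form X(t) for analysis-routine tests."""
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    Q = np.full_like(X, 0.5) if Q_X is None else np.asarray(Q_X, dtype=float)
    states = np.column_stack([X, Q])
    return Trajectory(
        times=t,
        states=states,
        state_names=("X", "Q_X"),
        u=np.full_like(t, u),
        extinct_at=None,
        equilibrated=False,
        settings_echo={"params": baseline().to_dict(), "rho": 20.0 / 3.0},
    )


@pytest.fixture
def make_traj():
    return synthetic_trajectory
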