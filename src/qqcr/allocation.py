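"""Optimal resource allocation between abundance and quality.

Under constant conditions, the allocation proportion maximising the
time-integral of log abundance drives the system to a singular-arc
equilibrium u = v*.  The singular conditions reduce to a closed form: with

    q_hat = sqrt(c mu / (a alpha)),     E = a alpha q_hat = sqrt(a alpha c mu),

the two candidate roots are

    v*(+/-) = (a mu +/- E) / (a mu +/- 2 E - alpha b).

They depend only on (a, b, c, alpha, mu) -- not on any extraction parameter
(delta, beta, gamma, K, w) -- which enables a mutual cross-check against a
numerical sweep of long-run equilibrium abundance over constant u: the
argmax of the sweep must coincide with the larger root.  Both checks are
implemented here; since the underlying optimality conditions are necessary
but not sufficient, both roots are always reported and the sweep
adjudicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integrate import AllocationPolicy, SolverSettings, Trajectory, simulate
from .params import ParameterSet

__all__ = ["VStarResult", "SweepResult", "v_star", "evaluate_J", "equilibrium_sweep_u"]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class VStarResult:
    """Candidate optimal constant allocations and their admissibility."""

    v_plus: float
    v_minus: float
    plus_admissible: bool
    minus_admissible: bool

    def as_tuple(self) -> tuple[float, float]:
        return self.v_plus, self.v_minus


def v_star(
    p: ParameterSet, u_min: float = 0.0, u_max: float = 1.0
) -> VStarResult:
    """Closed-form singular-arc allocation roots v*+ and v*-.

    Requires a, alpha, mu > 0.  Roots outside [u_min, u_max] (or complex /
    non-finite) are flagged inadmissible rather than dropped.
    """
    if p.a <= 0 or p.alpha <= 0 or p.mu <= 0:
        raise ValueError("v_star requires a > 0, alpha > 0, mu > 0")
    E = math.sqrt(p.a * p.alpha * p.c_bias * p.mu)
    am = p.a * p.mu
    ab = p.alpha * p.b_bias

    def root(sign: float) -> float:
        denom = am + sign * 2.0 * E - ab
        if denom == 0:
            return math.nan
        return (am + sign * E) / denom

    vp, vm = root(+1.0), root(-1.0)

    def ok(v: float) -> bool:
        return math.isfinite(v) and u_min <= v <= u_max

    return VStarResult(vp, vm, ok(vp), ok(vm))


def evaluate_J(traj: Trajectory, T: float | None = None) -> float:
    """Criterion J = integral of ln X(t) over [0, T] (trapezoidal).

    Returns -inf for trajectories extinct before T: the integrand is
    unbounded below as X -> 0, so extinction carries an infinite penalty.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    T = traj.times[-1] if T is None else float(T)
    if traj.extinct_at is not None and traj.extinct_at < T:
        return NEG_INF
    m = traj.times <= T + 1e-9
    t = traj.times[m]
    X = traj.X[m]
    if np.any(X <= 0):
        return NEG_INF
    return float(np.trapezoid(np.log(X), t))


@dataclass
class SweepResult:
    """Grid sweep of a scalar metric.

    ``grid`` is strictly increasing; ``metric`` has one entry per grid point
    (NaN where the run failed); ``flags`` records per-point status strings.
    """

    grid: np.ndarray
    metric: np.ndarray
    param: str = "u"
    metric_name: str = "equilibrium_abundance"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) != len(self.metric):
            raise ValueError("grid and metric must be 1-D and equally long")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not self.flags:
            self.flags = ["ok"] * len(self.grid)

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.nanargmax(self.metric))])

    @property
    def max(self) -> float:
        return float(np.nanmax(self.metric))

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.nanargmin(self.metric))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.param: self.grid, self.metric_name: self.metric, "flag": self.flags}
        )

    def save(self, path) -> None:
        from pathlib import Path
        import json

        base = Path(path)
        base = base.with_suffix("") if base.suffix == ".csv" else base
        self.to_frame().to_csv(base.with_suffix(".csv"), index=False, float_format="%.10g")
        summary = {
            "param": self.param,
            "metric": self.metric_name,
            "argmax": self.argmax,
            "max": self.max,
            "argmin": self.argmin,
        }
        base.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def _longrun_abundance(
    variant: str,
    p: ParameterSet,
    u: float,
    horizon: float,
    solver: SolverSettings,
    rho: float | None,
    polish: bool,
) -> tuple[float, str]:
    """Long-run consumer abundance at constant u, with root-polish fallback."""
    traj = simulate(
        variant, p, AllocationPolicy.constant(u), None, (0.0, horizon), solver, rho=rho
    )
    if traj.extinct_at is not None:
        return 0.0, "extinct"
    X_end = float(traj.X[-1])
    tail = traj.window(horizon - solver.equil_window)
    rel = abs(tail.X[-1] - tail.X[0]) / max(X_end, 1e-12)
    if rel < 1e-6:
        return (X_end if X_end >= solver.extinction else 0.0), "equilibrated"
    if polish:
        from .analysis import find_equilibrium  # deferred: avoids import cycle

        eq = find_equilibrium(variant, p, u, rho=rho, seed_state=traj.states[-1])
        if eq.converged and eq.X >= solver.extinction:
            return eq.X, "root-polished"
    return (X_end if X_end >= solver.extinction else 0.0), "not-converged"


def equilibrium_sweep_u(
    p: ParameterSet,
    u_grid,
    variant: str = "cr3",
    *,
    horizon: float = 600.0,
    solver: SolverSettings | None = None,
    rho: float | None = None,
    polish: bool = False,
) -> SweepResult:
    """Long-run consumer abundance for each constant allocation in ``u_grid``.

    Requires constant drivers (d_r = d_s = 0).  Each grid point integrates
    ``horizon`` months (default 600) from the standard initial conditions;
    runs that are not settled by then may optionally be polished by
    root-finding seeded with the simulation endpoint.  Values below the
    extinction cutoff report 0.
    """
    if p.d_r != 0 or p.d_s != 0:
        raise ValueError("equilibrium sweep requires constant drivers (d_r = d_s = 0)")
    solver = solver or SolverSettings(rtol=1e-7, atol=1e-9)
    grid = np.asarray(u_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("u grid must lie in [0, 1]")
    metric = np.empty_like(grid)
    flags: list[str] = []
    for i, u in enumerate(grid):
        try:
            metric[i], flag = _longrun_abundance(
                variant, p, float(u), horizon, solver, rho, polish
            )
        except RuntimeError as exc:  # per-point failure is isolated
            metric[i], flag = math.nan, f"failed: {exc}"
        flags.append(flag)
    return SweepResult(grid, metric, "u", "equilibrium_abundance", flags)
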