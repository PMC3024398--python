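"""Hybrid trajectory engine for the Q-Q models.

Integrates any model variant under an allocation policy, in log coordinates,
with event detection for the abundance-threshold switching surface, sliding
(Filippov) dynamics when both branch vector fields point at the surface,
and an extinction cutoff.

The threshold rule compares consumer abundance X with a critical level
``X_switch``; which bound applies below the threshold is the policy
``direction``:

* ``grow_below``    -- u = u_max for X <= X_switch (invest in abundance while
  small; clips peaks above the threshold).  This is the stabilising,
  peak-clipping rule.
* ``quality_below`` -- u = u_min for X <= X_switch (invest in quality while
  small; produces a lag phase followed by accelerated growth).

When the two branch fields both push X toward the surface, infinitely fast
chattering pins X at X_switch; the engine then follows the equivalent
(Filippov) dynamics: the convex combination of the two branch fields whose
X-component vanishes.  A literal chattering integrator with a capped step is
available via ``SolverSettings(sliding="chatter")``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import ModelVariant, make_variant
from .params import DEFAULT_INIT_CR, ParameterSet
from .rates import derived_rates

__all__ = [
    "AllocationPolicy",
    "SolverSettings",
    "Trajectory",
    "evaluate_policy",
    "simulate",
]


# --------------------------------------------------------------------------
# allocation policy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AllocationPolicy:
    """Constant or threshold-switching allocation rule.

    In threshold mode the boundary X = X_switch belongs to the "below"
    branch.
    """

    mode: str = "constant"
    u_const: float = 0.5
    u_min: float = 0.0
    u_max: float = 1.0
    X_switch: float = 0.0
    direction: str = "grow_below"
    hysteresis: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "threshold"):
            raise ValueError("mode must be 'constant' or 'threshold'")
        if self.mode == "constant":
            if not 0.0 <= self.u_const <= 1.0:
                raise ValueError("u_const must lie in [0, 1]")
        else:
            if not 0.0 <= self.u_min <= self.u_max <= 1.0:
                raise ValueError("need 0 <= u_min <= u_max <= 1")
            if self.X_switch < 0:
                raise ValueError("X_switch must be >= 0")
            if self.direction not in ("grow_below", "quality_below"):
                raise ValueError("direction must be 'grow_below' or 'quality_below'")
            if self.hysteresis < 0:
                raise ValueError("hysteresis must be >= 0")

    @classmethod
    def constant(cls, u: float) -> "AllocationPolicy":
        return cls(mode="constant", u_const=u)

    @classmethod
    def threshold(
        cls,
        u_min: float,
        u_max: float,
        X_switch: float,
        direction: str = "grow_below",
        hysteresis: float = 0.0,
    ) -> "AllocationPolicy":
        return cls(
            mode="threshold",
            u_min=u_min,
            u_max=u_max,
            X_switch=X_switch,
            direction=direction,
            hysteresis=hysteresis,
        )

    @property
    def u_below(self) -> float:
        return self.u_max if self.direction == "grow_below" else self.u_min

    @property
    def u_above(self) -> float:
        return self.u_min if self.direction == "grow_below" else self.u_max

    def evaluate(self, X: float) -> float:
        if X < 0:
            raise ValueError("X must be >= 0")
        if self.mode == "constant":
            return self.u_const
        return self.u_below if X <= self.X_switch else self.u_above


def evaluate_policy(X: float, policy: AllocationPolicy) -> float:
    """Allocation proportion applied at consumer abundance X."""
    return policy.evaluate(X)


# --------------------------------------------------------------------------
# solver settings and trajectory container
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the trajectory engine.

    method        -- 'LSODA' (default, auto-stiff) or any solve_ivp method.
    rtol, atol    -- tolerances of the adaptive solver.
    sample_dt     -- output sampling interval (months); dense output under it.
    extinction    -- abundance cutoff below which the consumer is extinct.
    sliding       -- 'filippov' (equivalent dynamics on the switching
                     surface) or 'chatter' (fixed-step integration with the
                     discontinuous rule, step capped at chatter_dt).
    chatter_dt    -- step cap used in chatter mode (months).
    equil_window  -- trailing window (months) for the equilibrated flag.
    equil_rtol    -- relative change defining equilibration.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: float = 1.0
    extinction: float = 1.0
    sliding: str = "filippov"
    chatter_dt: float = 0.01
    equil_window: float = 60.0
    equil_rtol: float = 1e-6
    max_step: float = math.inf

    def __post_init__(self) -> None:
        if self.sliding not in ("filippov", "chatter"):
            raise ValueError("sliding must be 'filippov' or 'chatter'")


@dataclass
class Trajectory:
    """Sampled solution of one simulation run.

    ``states`` holds natural coordinates (columns ``state_names``); ``u``
    the allocation applied at each sample (the sliding-segment effective
    value where applicable); ``extinct_at`` the first time X dropped below
    the cutoff (samples after it report X = 0).
    """

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]
    u: np.ndarray
    extinct_at: float | None
    equilibrated: bool
    settings_echo: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    @property
    def X(self) -> np.ndarray:
        return self["X"]

    @property
    def extinct(self) -> bool:
        return self.extinct_at is not None

    def window(self, t_start: float, t_end: float | None = None) -> "Trajectory":
        """Restrict to samples with t_start <= t <= t_end."""
        t_end = self.times[-1] if t_end is None else t_end
        m = (self.times >= t_start) & (self.times <= t_end)
        return Trajectory(
            self.times[m],
            self.states[m],
            self.state_names,
            self.u[m],
            self.extinct_at,
            self.equilibrated,
            self.settings_echo,
        )

    def to_frame(self) -> pd.DataFrame:
        """Fixed-layout frame: t, R, Q_R, X, Q_X, u, extinct.

        Components absent from the variant (e.g. R in the fixed-resource
        model) are filled with the constant background recorded in the
        settings echo.
        """
        n = len(self.times)
        cols: dict[str, np.ndarray] = {"t": self.times}
        echo = self.settings_echo
        background = {
            "R": echo.get("rho", np.nan) * echo.get("params", {}).get("beta", np.nan),
            "Q_R": 0.5,
        }
        for name in ("R", "Q_R", "X", "Q_X"):
            if name in self.state_names:
                cols[name] = self[name]
            else:
                cols[name] = np.full(n, background.get(name, np.nan))
        cols["u"] = self.u
        cols["extinct"] = (
            (self.times >= self.extinct_at).astype(int)
            if self.extinct_at is not None
            else np.zeros(n, dtype=int)
        )
        return pd.DataFrame(cols, columns=["t", "R", "Q_R", "X", "Q_X", "u", "extinct"])

    def save(self, path: str | Path) -> None:
        """Write <path>.csv (fixed columns) and <path>.json (settings echo)."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".csv" else path
        self.to_frame().to_csv(base.with_suffix(".csv"), index=False, float_format="%.10g")
        meta = dict(self.settings_echo)
        meta["extinct_at"] = self.extinct_at
        meta["equilibrated"] = self.equilibrated
        base.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))

    def derived(self) -> pd.DataFrame:
        """DerivedRates evaluated at every sample (coupled variants)."""
        p = ParameterSet.from_dict(self.settings_echo["params"])
        rows = []
        for i in range(len(self.times)):
            get = lambda nm, dflt: (
                self.states[i, self.state_names.index(nm)]
                if nm in self.state_names
                else dflt
            )
            X = get("X", math.nan)
            if self.extinct_at is not None and self.times[i] >= self.extinct_at:
                rows.append({k: 0.0 for k in (
                    "feeding", "F_norm", "I_rate", "theta", "m_decay", "g_rate", "kappa_eff")})
                continue
            d = derived_rates(
                get("R", self.settings_echo.get("rho", 0.0) * p.beta),
                X,
                get("Q_X", 1.0),
                get("Q_R", 0.5),
                self.u[i],
                p,
            )
            rows.append(asdict(d))
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# simulation engine
# --------------------------------------------------------------------------


def _as_variant(variant, p: ParameterSet, rho: float | None) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    return make_variant(variant, p, rho=rho)


def _init_to_log(variant: ModelVariant, init, p: ParameterSet) -> np.ndarray:
    if init is None:
        if variant.name == "fixed":
            init = {"X": DEFAULT_INIT_CR["X"], "Q_X": DEFAULT_INIT_CR["Q_X"]}
        else:
            init = {k: DEFAULT_INIT_CR[k] for k in variant.state_names}
    if isinstance(init, dict):
        vec = [init[k] for k in variant.state_names]
    elif hasattr(init, "__dataclass_fields__"):
        vec = [getattr(init, k) for k in variant.state_names]
    else:
        vec = list(init)
    arr = np.asarray(vec, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("initial state components must be positive")
    return np.log(arr)


def simulate(
    variant,
    p: ParameterSet,
    policy: AllocationPolicy | float = 0.5,
    init=None,
    t_span: tuple[float, float] | float = 300.0,
    solver: SolverSettings | None = None,
    *,
    rho: float | None = None,
) -> Trajectory:
    """Integrate a model variant under an allocation policy.

    Parameters
    ----------
    variant : str or ModelVariant
        'fixed', 'cr3' or 'cr4' (or a pre-bound variant).
    policy : AllocationPolicy or float
        A float is shorthand for a constant-allocation policy.
    init : dict, dataclass, sequence or None
        Initial state in natural coordinates; ``None`` uses the standard
        initial conditions (R=2e5, X=1e4, Q_X=0.45, Q_R=0.5).
    t_span : (t0, t1) or horizon t1 (months).
    rho : float, optional
        Constant resource background for the fixed variant (R/beta).

    Identical inputs produce identical outputs; the run is fully
    deterministic.
    """
    if isinstance(policy, (int, float)):
        policy = AllocationPolicy.constant(float(policy))
    solver = solver or SolverSettings()
    mv = _as_variant(variant, p, rho)
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1) and t1 >= t0):
        raise ValueError("t_span must be finite with t1 >= t0")

    y0 = _init_to_log(mv, init, p)
    times = np.arange(t0, t1 + 0.5 * solver.sample_dt, solver.sample_dt)
    if t1 == t0:
        times = np.array([t0])

    if t1 == t0:
        ys = y0[None, :]
        u_out = np.array([policy.evaluate(float(np.exp(y0[mv.x_index])))])
        extinct_at = None
    elif policy.mode == "constant":
        ys, u_out, extinct_at = _run_constant(mv, p, policy.u_const, y0, times, solver)
    elif solver.sliding == "chatter":
        ys, u_out, extinct_at = _run_chatter(mv, p, policy, y0, times, solver)
    else:
        ys, u_out, extinct_at = _run_threshold(mv, p, policy, y0, times, solver)

    states = np.exp(ys)
    if extinct_at is not None:
        states[times >= extinct_at, mv.x_index] = 0.0

    equilibrated = _equilibrated(times, states[:, mv.x_index], solver) and extinct_at is None
    echo: dict[str, Any] = {
        "variant": mv.name,
        "params": p.to_dict(),
        "policy": asdict(policy),
        "solver": asdict(solver),
        "t_span": [t0, t1],
        "init": {k: float(v) for k, v in zip(mv.state_names, np.exp(y0))},
    }
    if mv.name == "fixed":
        echo["rho"] = (2.0e5 / p.beta) if rho is None else float(rho)
    return Trajectory(times, states, mv.state_names, u_out, extinct_at, equilibrated, echo)


def _equilibrated(times: np.ndarray, X: np.ndarray, solver: SolverSettings) -> bool:
    """Flag: X varies by less than 1e-4 (relative) over the trailing window."""
    if len(times) < 3 or times[-1] - times[0] < solver.equil_window:
        return False
    m = times >= times[-1] - solver.equil_window
    Xw = X[m]
    base = max(abs(Xw[-1]), 1e-12)
    return bool(np.max(np.abs(Xw - Xw[-1])) / base < 1e-4)


def _ivp_kwargs(solver: SolverSettings) -> dict:
    kw = dict(method=solver.method, rtol=solver.rtol, atol=solver.atol)
    if math.isfinite(solver.max_step):
        kw["max_step"] = solver.max_step
    return kw


def _run_constant(mv, p, u, y0, times, solver):
    cutoff = math.log(max(solver.extinction, 1e-12))

    def ext_event(t, y):
        return y[mv.x_index] - cutoff

    ext_event.terminal = True
    ext_event.direction = -1.0

    sol = solve_ivp(
        lambda t, y: mv.rhs(t, y, u),
        (times[0], times[-1]),
        y0,
        t_eval=times,
        events=[ext_event],
        dense_output=False,
        **_ivp_kwargs(solver),
    )
    if sol.status == -1:
        raise RuntimeError(
            f"solver failed at t={sol.t[-1] if len(sol.t) else times[0]:.3f}: "
            f"{sol.message}; last state (log) {sol.y[:, -1] if sol.y.size else y0}"
        )
    n = len(times)
    ys = np.full((n, len(y0)), np.nan)
    got = len(sol.t)
    ys[:got] = sol.y.T
    extinct_at = None
    if sol.status == 1:  # extinction event
        extinct_at = float(sol.t_events[0][0])
        ys[got:] = ys[got - 1] if got else y0
    u_out = np.full(n, float(u))
    return ys, u_out, extinct_at


# ---- threshold mode with Filippov sliding ---------------------------------


def _run_threshold(mv, p, policy, y0, times, solver):
    xi = mv.x_index
    lsw = math.log(policy.X_switch) if policy.X_switch > 0 else -math.inf
    cutoff = math.log(max(solver.extinction, 1e-12))
    u_below, u_above = policy.u_below, policy.u_above

    n = len(times)
    ys = np.full((n, len(y0)), np.nan)
    u_out = np.full(n, np.nan)
    filled = 0
    extinct_at = None

    t = times[0]
    y = y0.copy()
    # classify the initial regime; surface itself counts as "below"
    mode = "below" if y[xi] <= lsw else "above"
    guard = 0

    def record(sol, u_f, t_end):
        """Sample the solved segment onto the global grid."""
        nonlocal filled
        while filled < n and times[filled] <= t_end + 1e-9:
            tv = min(max(times[filled], sol.t[0]), sol.t[-1])
            yv = sol.sol(tv)
            ys[filled] = yv
            u_out[filled] = u_f(tv, yv)
            filled += 1

    while t < times[-1] - 1e-9:
        guard += 1
        if guard > 100000:
            raise RuntimeError("switching iteration cap exceeded (chattering too fast?)")
        if mode in ("below", "above"):
            u = u_below if mode == "below" else u_above
            # with a hysteresis band, the branch persists until the far edge
            if policy.hysteresis > 0 and math.isfinite(lsw):
                edge = policy.X_switch * (
                    1 + policy.hysteresis if mode == "below" else 1 - policy.hysteresis
                )
                lsurf = math.log(edge)
            else:
                lsurf = lsw

            def surf(tt, yy):
                return yy[xi] - lsurf

            surf.terminal = True
            surf.direction = 1.0 if mode == "below" else -1.0

            def ext(tt, yy):
                return yy[xi] - cutoff

            ext.terminal = True
            ext.direction = -1.0

            events = [surf, ext] if math.isfinite(lsw) else [ext]
            sol = solve_ivp(
                lambda tt, yy: mv.rhs(tt, yy, u),
                (t, times[-1]),
                y,
                events=events,
                dense_output=True,
                **_ivp_kwargs(solver),
            )
            if sol.status == -1:
                raise RuntimeError(f"solver failed at t={sol.t[-1]:.3f}: {sol.message}")
            t_end = sol.t[-1]
            record(sol, lambda tv, yv, _u=u: _u, t_end)
            y = sol.y[:, -1].copy()
            t = t_end
            if sol.status == 1:
                hit_surface = math.isfinite(lsurf) and len(sol.t_events[0]) > 0
                if hit_surface:
                    y[xi] = lsurf  # land exactly on the surface
                    if policy.hysteresis > 0:
                        mode = "above" if mode == "below" else "below"
                    else:
                        dxb = mv.rhs(t, y, u_below)[xi]
                        dxa = mv.rhs(t, y, u_above)[xi]
                        if dxb > 0.0 > dxa:
                            mode = "slide"
                        else:
                            mode = "above" if mode == "below" else "below"
                            # nudge off the surface to avoid immediate re-trigger
                            y[xi] += 1e-12 if mode == "above" else -1e-12
                else:
                    extinct_at = float(sol.t_events[-1][0])
                    break
        else:  # sliding along X = X_switch
            def slide_rhs(tt, yy):
                fb = mv.rhs(tt, yy, u_below)
                fa = mv.rhs(tt, yy, u_above)
                denom = fa[xi] - fb[xi]
                s = fa[xi] / denom if denom != 0 else 0.5
                s = min(max(s, 0.0), 1.0)
                d = s * fb + (1.0 - s) * fa
                d[xi] = 0.0  # pinned to the surface
                return d

            def exit_down(tt, yy):
                return mv.rhs(tt, yy, u_below)[xi]

            exit_down.terminal = True
            exit_down.direction = -1.0

            def exit_up(tt, yy):
                return mv.rhs(tt, yy, u_above)[xi]

            exit_up.terminal = True
            exit_up.direction = 1.0

            y[xi] = lsw

            def u_eff(tv, yv):
                fb = mv.rhs(tv, yv, u_below)
                fa = mv.rhs(tv, yv, u_above)
                denom = fa[xi] - fb[xi]
                s = fa[xi] / denom if denom != 0 else 0.5
                s = min(max(s, 0.0), 1.0)
                return s * u_below + (1.0 - s) * u_above

            sol = solve_ivp(
                slide_rhs,
                (t, times[-1]),
                y,
                events=[exit_down, exit_up],
                dense_output=True,
                **_ivp_kwargs(solver),
            )
            if sol.status == -1:
                raise RuntimeError(f"solver failed while sliding at t={sol.t[-1]:.3f}: {sol.message}")
            t_end = sol.t[-1]
            record(sol, u_eff, t_end)
            y = sol.y[:, -1].copy()
            y[xi] = lsw
            t = t_end
            if sol.status == 1:
                if len(sol.t_events[0]) > 0:  # below-field turned negative: drop off
                    mode = "below"
                    y[xi] = lsw - 1e-12
                else:  # above-field turned positive: lift off
                    mode = "above"
                    y[xi] = lsw + 1e-12

    # pad any remaining samples (extinction or numerical shortfall)
    if filled < n:
        last = ys[filled - 1] if filled else y0
        ys[filled:] = last
        u_out[filled:] = u_out[filled - 1] if filled else policy.evaluate(float(np.exp(y0[xi])))
    return ys, u_out, extinct_at


# ---- literal chattering integrator ----------------------------------------


def _run_chatter(mv, p, policy, y0, times, solver):
    """Fixed-step RK4 with the discontinuous rule, step capped at chatter_dt."""
    xi = mv.x_index
    cutoff = math.log(max(solver.extinction, 1e-12))
    dt = solver.chatter_dt
    n = len(times)
    ys = np.full((n, len(y0)), np.nan)
    u_out = np.full(n, np.nan)
    y = y0.copy()
    t = times[0]
    k = 0
    extinct_at = None
    while k < n:
        if times[k] <= t + 1e-12:
            ys[k] = y
            u_out[k] = policy.evaluate(float(np.exp(y[xi])))
            k += 1
            continue
        h = min(dt, times[k] - t)
        u = policy.evaluate(float(np.exp(y[xi])))
        k1 = mv.rhs(t, y, u)
        k2 = mv.rhs(t + h / 2, y + h / 2 * k1, u)
        k3 = mv.rhs(t + h / 2, y + h / 2 * k2, u)
        k4 = mv.rhs(t + h, y + h * k3, u)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if y[xi] < cutoff:
            extinct_at = t
            ys[k:] = y
            u_out[k:] = u
            break
    return ys, u_out, extinct_at
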