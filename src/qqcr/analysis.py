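"""Post-simulation analysis: equilibria, stability, periods, growth phases.

Everything here operates on autonomous configurations (constant drivers) or
on sampled :class:`~qqcr.integrate.Trajectory` objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.signal import find_peaks, periodogram

from .allocation import SweepResult
from .integrate import AllocationPolicy, SolverSettings, Trajectory, simulate
from .models import make_variant
from .params import ParameterSet

__all__ = [
    "Equilibrium",
    "StabilityResult",
    "PeriodEstimate",
    "SummaryStats",
    "PhaseSegmentation",
    "find_equilibrium",
    "stability_spectrum",
    "estimate_period",
    "summary_stats",
    "classify_growth_phases",
    "parameter_sweep",
]

MONTHS_PER_YEAR = 12.0


# --------------------------------------------------------------------------
# equilibria and stability
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Equilibrium:
    """An interior equilibrium (or the report that none was found)."""

    state_names: tuple[str, ...]
    state: np.ndarray | None
    residual: float
    converged: bool
    message: str = ""

    @property
    def X(self) -> float:
        if self.state is None:
            return math.nan
        return float(self.state[self.state_names.index("X")])

    def __getitem__(self, name: str) -> float:
        if self.state is None:
            raise KeyError("no equilibrium state")
        return float(self.state[self.state_names.index(name)])


def find_equilibrium(
    variant: str,
    p: ParameterSet,
    u: float,
    *,
    rho: float | None = None,
    seed_state=None,
    seed_horizon: float = 400.0,
    residual_tol: float = 1e-10,
) -> Equilibrium:
    """Interior equilibrium of an autonomous variant at constant u.

    The root search runs in log coordinates, seeded by the endpoint of a
    moderate simulation (or a caller-supplied state).  An equilibrium is
    accepted only if the RHS residual norm is below ``residual_tol``; at the
    allocation boundaries (u = 0 or 1) no interior equilibrium exists and an
    explicit report is returned.
    """
    if p.d_r != 0 or p.d_s != 0:
        raise ValueError("find_equilibrium requires constant drivers")
    mv = make_variant(variant, p, rho=rho)
    if not 0.0 < u < 1.0:
        return Equilibrium(
            mv.state_names, None, math.inf, False,
            "no interior equilibrium at the allocation boundary u in {0, 1}",
        )
    if seed_state is None:
        traj = simulate(
            variant, p, AllocationPolicy.constant(u), None,
            (0.0, seed_horizon), SolverSettings(rtol=1e-8, atol=1e-10), rho=rho,
        )
        if traj.extinct_at is not None:
            return Equilibrium(
                mv.state_names, None, math.inf, False,
                f"trajectory extinct at t={traj.extinct_at:.1f}; no interior equilibrium found",
            )
        y0 = np.log(traj.states[-1])
    else:
        y0 = np.log(np.asarray(seed_state, dtype=float))

    fun = lambda y: mv.rhs(0.0, y, u)
    sol = root(fun, y0, method="hybr", tol=1e-13)
    res = float(np.linalg.norm(fun(sol.x)))
    if res > residual_tol:  # residual is the criterion; scipy's own flag can
        # report "slow progress" even at a converged root
        return Equilibrium(
            mv.state_names, None, res, False,
            f"root search did not converge (residual {res:.2e}): {sol.message}",
        )
    state = np.exp(sol.x)
    return Equilibrium(mv.state_names, state, res, True)


@dataclass(frozen=True)
class StabilityResult:
    """Eigenvalues of the Jacobian at an interior equilibrium."""

    eigenvalues: np.ndarray
    classification: str
    equilibrium: Equilibrium
    condition: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    @property
    def oscillatory(self) -> bool:
        return bool(np.any(np.abs(self.eigenvalues.imag) > 1e-12))

    @property
    def ringing_period_years(self) -> float:
        """2 pi / omega of the dominant complex pair (inf if none)."""
        w = float(np.max(np.abs(self.eigenvalues.imag)))
        return math.inf if w == 0 else 2.0 * math.pi / w / MONTHS_PER_YEAR


def _num_jacobian(fun, y0: np.ndarray, h: float = 1e-6) -> np.ndarray:
    n = len(y0)
    J = np.empty((n, n))
    for j in range(n):
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2.0 * h)
    return J


def stability_spectrum(
    variant: str,
    p: ParameterSet,
    u: float,
    *,
    rho: float | None = None,
    equilibrium: Equilibrium | None = None,
) -> StabilityResult:
    """Eigenvalues of the (central-difference) Jacobian at the equilibrium.

    The Jacobian is taken in log coordinates, where the flow is smooth and
    the spectrum classifies local behaviour: stable/unstable node or focus.
    An ill-conditioned Jacobian is flagged through the ``condition`` field.
    """
    eq = equilibrium or find_equilibrium(variant, p, u, rho=rho)
    if not eq.converged:
        raise ValueError(f"no interior equilibrium: {eq.message}")
    mv = make_variant(variant, p, rho=rho)
    y0 = np.log(eq.state)
    J = _num_jacobian(lambda y: mv.rhs(0.0, y, u), y0)
    ev = np.linalg.eigvals(J)
    cond = float(np.linalg.cond(J))
    osc = np.any(np.abs(ev.imag) > 1e-12)
    if np.all(ev.real < 0):
        cls = "stable focus" if osc else "stable node"
    elif np.all(ev.real > 0):
        cls = "unstable focus" if osc else "unstable node"
    else:
        cls = "unstable focus" if osc else "saddle"
    return StabilityResult(ev, cls, eq, cond)


# --------------------------------------------------------------------------
# period estimation and window statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodEstimate:
    """Oscillation period of consumer abundance.

    ``period`` is in years (None when the trajectory is equilibrated or has
    fewer than three peaks); ``spectral`` is an independent dominant-period
    cross-check from the periodogram.
    """

    period: float | None
    n_peaks: int
    method: str
    window: tuple[float, float]
    spectral: float | None = None

    @property
    def rounded(self) -> float | None:
        """Period to 0.1 year, the precision at which periods are quoted."""
        return None if self.period is None else round(self.period, 1)


def estimate_period(
    traj: Trajectory,
    window: float | tuple[float, float] | None = None,
    *,
    prominence_frac: float = 0.05,
    method: str = "inter-peak",
    min_distance_months: float | None = None,
) -> PeriodEstimate:
    """Mean inter-peak interval of X maxima, in years.

    ``window`` selects the analysed span: a pair (t0, t1), a single number
    meaning "the final `window` months", or None for the second half of the
    trajectory (transient discarded).  Peaks are prominence-filtered at 5%
    of the windowed range; fewer than three peaks yield no estimate.
    ``min_distance_months`` suppresses peaks closer than the given spacing,
    e.g. 18 months to isolate a multi-year cycle from an annual imprint.
    """
    t_all = traj.times
    if window is None:
        w0, w1 = t_all[0] + (t_all[-1] - t_all[0]) / 2.0, t_all[-1]
    elif np.isscalar(window):
        w0, w1 = t_all[-1] - float(window), t_all[-1]
    else:
        w0, w1 = float(window[0]), float(window[1])
    sub = traj.window(w0, w1)
    t, X = sub.times, sub.X
    if len(t) < 8:
        return PeriodEstimate(None, 0, method, (w0, w1))
    rng = float(X.max() - X.min())
    if rng <= 1e-9 * max(abs(X.mean()), 1e-12):
        return PeriodEstimate(None, 0, method, (w0, w1))  # constant/equilibrated

    kw = {}
    if min_distance_months is not None:
        dt = float(np.median(np.diff(t)))
        kw["distance"] = max(int(min_distance_months / dt), 1)
    peaks, _ = find_peaks(X, prominence=prominence_frac * rng, **kw)
    spectral = _spectral_period(t, X)
    if method == "spectral":
        return PeriodEstimate(spectral, len(peaks), "spectral", (w0, w1), spectral)
    if len(peaks) < 3:
        return PeriodEstimate(None, len(peaks), method, (w0, w1), spectral)
    period = float(np.mean(np.diff(t[peaks]))) / MONTHS_PER_YEAR
    return PeriodEstimate(period, len(peaks), method, (w0, w1), spectral)


def _spectral_period(t: np.ndarray, X: np.ndarray) -> float | None:
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        return None
    f, P = periodogram(X - X.mean(), fs=1.0 / dt)
    if len(f) < 3:
        return None
    i = int(np.argmax(P[1:])) + 1
    if f[i] == 0:
        return None
    return float(1.0 / f[i]) / MONTHS_PER_YEAR


@dataclass(frozen=True)
class SummaryStats:
    """Windowed statistics of consumer abundance."""

    min: float
    max: float
    mean: float
    sigma: float
    n_samples: int
    sample_dt: float
    window: tuple[float, float]


def summary_stats(
    traj: Trajectory, window: float | tuple[float, float] | None = None
) -> SummaryStats:
    """(min, max, mean, sigma) of X over the requested window."""
    t_all = traj.times
    if window is None:
        w0, w1 = t_all[0], t_all[-1]
    elif np.isscalar(window):
        w0, w1 = t_all[-1] - float(window), t_all[-1]
    else:
        w0, w1 = float(window[0]), float(window[1])
    sub = traj.window(w0, w1)
    if len(sub.times) == 0:
        raise ValueError("window contains no samples")
    X = sub.X
    dt = float(np.median(np.diff(sub.times))) if len(sub.times) > 1 else math.nan
    return SummaryStats(
        float(X.min()), float(X.max()), float(X.mean()), float(X.std()),
        len(X), dt, (w0, w1),
    )


# --------------------------------------------------------------------------
# growth-phase classification
# --------------------------------------------------------------------------

PHASE_LABELS = ("lag", "LogEx", "RegEx", "inhibition", "stationary", "decline")


@dataclass(frozen=True)
class PhaseSegment:
    label: str
    t_start: float
    t_end: float


@dataclass
class PhaseSegmentation:
    """Ordered, contiguous growth-phase segments covering the window."""

    segments: list[PhaseSegment] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def segment(self, label: str) -> PhaseSegment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)


def classify_growth_phases(
    traj: Trajectory,
    *,
    lag_frac: float = 0.25,
    regex_frac: float = 0.05,
    stationary_frac: float = 0.02,
) -> PhaseSegmentation:
    """Segment a growth trajectory by its per-capita growth rate.

    The per-capita rate g = d ln X / dt is estimated by finite differences
    and the trajectory is split into: lag (g below ``lag_frac`` of its later
    maximum), LogEx (g rising to its maximum), RegEx (g approximately
    constant: |dg/dt| below ``regex_frac`` of its LogEx-phase maximum),
    inhibition (g decreasing but positive), stationary (|g| within
    ``stationary_frac`` of the maximum rate of zero) and decline (g < 0).
    These thresholds are heuristics for qualitatively defined phases.
    """
    t, X = traj.times, traj.X
    if len(t) < 8 or np.any(X <= 0):
        return PhaseSegmentation(
            [PhaseSegment("unclassified", float(t[0]), float(t[-1]))]
        )
    g_raw = np.gradient(np.log(X), t)
    # light smoothing with edge padding so the boundary samples are not damped
    k = 5
    padded = np.concatenate([np.full(k // 2, g_raw[0]), g_raw, np.full(k // 2, g_raw[-1])])
    g = np.convolve(padded, np.ones(k) / k, mode="valid")
    dg = np.gradient(g, t)
    if float(np.max(np.abs(g))) < 1e-12:  # numerically flat
        return PhaseSegmentation([PhaseSegment("stationary", float(t[0]), float(t[-1]))])
    gmax = float(np.max(g))
    if gmax <= 0:
        lbl = "decline" if np.all(g < 0) else "stationary"
        return PhaseSegmentation([PhaseSegment(lbl, float(t[0]), float(t[-1]))])
    i_peak = int(np.argmax(g))
    eps = stationary_frac * gmax
    dg_scale = float(np.max(np.abs(dg)))

    labels = []
    for i in range(len(t)):
        gi, dgi = g[i], dg[i]
        if gi < -eps:
            labels.append("decline")
        elif i < i_peak and gi < lag_frac * gmax:
            labels.append("lag")
        elif abs(gi) <= eps:
            labels.append("stationary")
        elif abs(dgi) <= regex_frac * dg_scale:
            labels.append("RegEx")
        elif dgi > 0 and i <= i_peak:
            labels.append("LogEx")
        elif dgi < 0:
            labels.append("inhibition")
        else:
            labels.append("RegEx")

    segs: list[PhaseSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append(PhaseSegment(labels[start], float(t[start]), float(t[min(i, len(t) - 1)])))
            start = i
    # merge micro-segments (shorter than 3 samples or 0.5% of the window)
    span = t[-1] - t[0]
    min_len = max(3.0 * float(np.median(np.diff(t))), 0.005 * span)
    merged: list[PhaseSegment] = []
    for s in segs:
        tiny = (s.t_end - s.t_start) < min_len
        if merged and tiny:
            prev = merged[-1]
            merged[-1] = PhaseSegment(prev.label, prev.t_start, s.t_end)
        elif merged and merged[-1].label == s.label:
            merged[-1] = PhaseSegment(s.label, merged[-1].t_start, s.t_end)
        elif not merged and tiny and len(segs) > 1:
            merged.append(PhaseSegment("", s.t_start, s.t_end))  # fold into next
        else:
            if merged and merged[-1].label == "":
                merged[-1] = PhaseSegment(s.label, merged[-1].t_start, s.t_end)
            else:
                merged.append(s)
    return PhaseSegmentation(merged)


# --------------------------------------------------------------------------
# generic parameter sweeps
# --------------------------------------------------------------------------

_METRICS = ("period", "extinction", "mean", "sigma", "equilibrium")


def parameter_sweep(
    variant: str,
    p: ParameterSet,
    param: str,
    grid,
    metric: str = "period",
    *,
    policy: AllocationPolicy | float = 0.5,
    horizon: float | None = None,
    window: float | None = None,
    solver: SolverSettings | None = None,
    rho: float | None = None,
) -> SweepResult:
    """One metric per grid point of a parameter scan.

    Metrics: 'period' (years; NaN when no sustained cycle / extinct),
    'extinction' (earliest time X < cutoff, NaN if never), 'mean' and
    'sigma' of X over the analysis window, 'equilibrium' (long-run
    abundance, 0 when extinct).  Transient discard: the first 80 years for
    seasonally forced runs, otherwise the first half of the horizon.
    Failures are isolated per point and recorded in the flags.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    grid = np.asarray(grid, dtype=float)
    if isinstance(policy, (int, float)):
        policy = AllocationPolicy.constant(float(policy))
    solver = solver or SolverSettings(rtol=1e-7, atol=1e-9)
    vals = np.empty_like(grid)
    flags: list[str] = []
    for i, g in enumerate(grid):
        try:
            pp = p.with_(**{param: float(g)})
            forced = pp.d_r > 0 or pp.d_s > 0
            hz = horizon if horizon is not None else (1200.0 if forced else 2400.0)
            traj = simulate(variant, pp, policy, None, (0.0, hz), solver, rho=rho)
            if window is not None:
                w0 = hz - window
            elif forced:
                w0 = min(80.0 * 12, 0.8 * hz)
            else:
                w0 = hz / 2.0
            flag = "ok"
            if metric == "extinction":
                vals[i] = traj.extinct_at if traj.extinct_at is not None else math.nan
                flag = "extinct" if traj.extinct_at is not None else "survives"
            elif traj.extinct_at is not None:
                vals[i] = 0.0 if metric in ("mean", "sigma", "equilibrium") else math.nan
                flag = "extinct"
            elif metric == "period":
                est = estimate_period(traj, (w0, hz))
                vals[i] = est.period if est.period is not None else math.nan
                flag = "ok" if est.period is not None else "no-cycle"
            elif metric == "mean":
                vals[i] = summary_stats(traj, (w0, hz)).mean
            elif metric == "sigma":
                vals[i] = summary_stats(traj, (w0, hz)).sigma
            else:  # equilibrium
                vals[i] = float(traj.X[-1])
        except (RuntimeError, ValueError) as exc:
            vals[i] = math.nan
            flag = f"failed: {exc}"
        flags.append(flag)
    return SweepResult(grid, vals, param, metric, flags)
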