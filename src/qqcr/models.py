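"""State types and right-hand sides of the three Q-Q model variants.

Variants
--------
``fixed``   two-state (x, q) = (ln X, ln Q_X) consumer on a constant resource
            background rho = R/beta;
``cr3``     three-state (R, X, Q_X) seasonal reduction: logistic resource with
            forced carrying capacity S(t) and forced resource quality Q_R(t);
``cr4``     four-state (R, Q_R, X, Q_X): the resource is itself a Q-Q
            population (metaphysiological growth on a substrate background,
            dynamic quality), harvested by the consumer.

All integration is done in log coordinates (ln R, ln X, q = ln Q) so that
positivity and the quality bound Q <= 1 hold structurally: at q = 0 the
quality derivative is -c*mu < 0, so q cannot cross zero.

The quantitative core, for applied allocation u and converted intake
I = kappa_eff * f(R, X) * R with kappa_eff = kappa(Q_R) * sech(w (u - v)):

    dx/dt = u I - mu + alpha q - eps            (abundance; decay theta = -alpha q)
    dq/dt = a (-q)(1 - u) I - c mu - b alpha q  (average quality)

The four-state variant applies the same two equations to the resource, with
the substrate level in the consumer role of R; setting its growth to the
logistic form and freezing Q_R to the seasonal driver reproduces ``cr3``
exactly (asserted in the test-suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .rates import allocation_efficiency, resource_quality_conversion

__all__ = [
    "StateQQ",
    "StateCR3",
    "StateCR4",
    "rhs_fixed_resource",
    "rhs_seasonal_3d",
    "rhs_full_4d",
    "ModelVariant",
    "make_variant",
    "VARIANT_NAMES",
]

_TWO_PI = 2.0 * math.pi


# --------------------------------------------------------------------------
# state records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StateQQ:
    """Log abundance x = ln X and log quality q = ln Q_X (q <= 0)."""

    x: float
    q: float

    def __post_init__(self) -> None:
        if self.q > 0:
            raise ValueError("log quality q must be <= 0")
        if not math.isfinite(self.x):
            raise ValueError("x must be finite")


@dataclass(frozen=True)
class StateCR3:
    """Resource abundance R > 0, consumer abundance X >= 0, quality Q_X in (0, 1]."""

    R: float
    X: float
    Q_X: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.X < 0:
            raise ValueError("X must be >= 0")
        if not 0 < self.Q_X <= 1:
            raise ValueError("Q_X must lie in (0, 1]")


@dataclass(frozen=True)
class StateCR4:
    """Four-state record: adds resource quality Q_R in (0, 1]."""

    R: float
    Q_R: float
    X: float
    Q_X: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.X < 0:
            raise ValueError("X must be >= 0")
        if not 0 < self.Q_X <= 1:
            raise ValueError("Q_X must lie in (0, 1]")
        if not 0 < self.Q_R <= 1:
            raise ValueError("Q_R must lie in (0, 1]")


# --------------------------------------------------------------------------
# scalar helpers
# --------------------------------------------------------------------------


def _drivers(t: float, p: ParameterSet) -> tuple[float, float]:
    s = math.sin(_TWO_PI * t / p.period)
    return p.S0 * (1.0 + 2.0 * p.d_s * s), 0.5 + p.d_r * s


def _qq_core(
    q: float, I: float, u: float, p: ParameterSet
) -> tuple[float, float]:
    """(dx/dt, dq/dt) of the Q-Q core given converted intake I."""
    dx = u * I - p.mu + p.alpha * q - p.eps_removal
    dq = p.a * (-q) * (1.0 - u) * I - p.c_bias * p.mu - p.b_bias * p.alpha * q
    return dx, dq


def _intake(lR: float, lX: float, QR: float, u: float, p: ParameterSet) -> tuple[float, float]:
    """(converted intake I, harvest per unit resource f*X) at a log state."""
    rho = math.exp(lR) / p.beta
    s = math.exp(p.gamma * lX) / p.k_interference
    F = rho / (1.0 + rho + s)  # normalised functional response in [0, 1)
    I = resource_quality_conversion(QR, p) * allocation_efficiency(u, p) * p.delta * F
    harvest = p.delta * F * math.exp(lX - lR)  # f(R,X)*X per unit resource
    return I, harvest


# --------------------------------------------------------------------------
# natural-coordinate right-hand sides (the spec'd operations)
# --------------------------------------------------------------------------


def rhs_fixed_resource(
    s: StateQQ, u: float, rho: float, p: ParameterSet
) -> tuple[float, float]:
    """(dx/dt, dq/dt) of the fixed-resource two-state model.

    ``rho`` is the constant normalised resource background R/beta.  The
    conversion coefficient is ``p.kappa_fixed``.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    return tuple(_rhs_fixed_log(0.0, np.array([s.x, s.q]), u, p, rho))


def rhs_seasonal_3d(
    s: StateCR3, t: float, u: float, p: ParameterSet
) -> tuple[float, float, float]:
    """(dR/dt, dX/dt, dQ_X/dt) of the seasonal three-state reduction."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    if s.X == 0.0:
        S, _ = _drivers(t, p)
        q = math.log(s.Q_X)
        dQ = s.Q_X * (-p.c_bias * p.mu - p.b_bias * p.alpha * q)
        return p.r * s.R * (1.0 - s.R / S), 0.0, dQ
    y = np.array([math.log(s.R), math.log(s.X), math.log(s.Q_X)])
    d = _rhs_cr3_log(t, y, u, p)
    return float(d[0] * s.R), float(d[1] * s.X), float(d[2] * s.Q_X)


def rhs_full_4d(
    s: StateCR4,
    t: float,
    u: float,
    p: ParameterSet,
    *,
    logistic_resource: bool = False,
    frozen_Q_R: bool = False,
) -> tuple[float, float, float, float]:
    """(dR/dt, dQ_R/dt, dX/dt, dQ_X/dt) of the four-state model.

    With ``logistic_resource=True`` and ``frozen_Q_R=True`` the resource
    subsystem degenerates to the seasonal reduction: the growth term becomes
    the logistic r(1 - R/S(t)) and dQ_R/dt follows the seasonal driver, so the
    remaining equations coincide with :func:`rhs_seasonal_3d` exactly.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    lX = math.log(s.X) if s.X > 0 else -math.inf
    y = np.array([math.log(s.R), math.log(s.Q_R), lX, math.log(s.Q_X)])
    d = _rhs_cr4_log(t, y, u, p, logistic_resource, frozen_Q_R)
    return (
        float(d[0] * s.R),
        float(d[1] * s.Q_R),
        float(d[2] * s.X) if s.X > 0 else 0.0,
        float(d[3] * s.Q_X),
    )


# --------------------------------------------------------------------------
# log-coordinate vector fields (what the integrator consumes)
# --------------------------------------------------------------------------


def _rhs_fixed_log(t, y, u, p: ParameterSet, rho: float):
    x, q = float(y[0]), float(y[1])
    sgam = math.exp(p.gamma * x) / p.k_interference
    F = rho / (1.0 + rho + sgam)
    I = p.kappa_fixed * allocation_efficiency(u, p) * p.delta * F
    dx, dq = _qq_core(q, I, u, p)
    return np.array([dx, dq])


def _rhs_cr3_log(t, y, u, p: ParameterSet):
    lR, lX, q = float(y[0]), float(y[1]), float(y[2])
    S, QR = _drivers(t, p)
    I, harvest = _intake(lR, lX, QR, u, p)
    dx, dq = _qq_core(q, I, u, p)
    dlR = p.r * (1.0 - math.exp(lR) / S) - harvest
    return np.array([dlR, dx, dq])


def _rhs_cr4_log(
    t, y, u, p: ParameterSet, logistic_resource: bool, frozen_Q_R: bool
):
    lR, qR, lX, qX = (float(v) for v in y)
    S, QR_driver = _drivers(t, p)

    QR = QR_driver if frozen_Q_R else math.exp(qR)
    if lX > -math.inf:
        I, harvest = _intake(lR, lX, QR, u, p)
        dx, dqX = _qq_core(qX, I, u, p)
    else:  # consumer absent
        dx, dqX = 0.0, -p.c_bias * p.mu - p.b_bias * p.alpha * qX
        harvest = 0.0

    if logistic_resource:
        growth = p.r * (1.0 - math.exp(lR) / S)
    else:
        # resource as a Q-Q population on a substrate background at level S(t):
        # reduced extraction I(R) with the resource in the consumer role.
        sigma = S / p.beta
        sgam = math.exp(p.gamma * lR) / (p.K_resource_dd**p.gamma)
        F_R = sigma / (1.0 + sigma + sgam)
        I_R = p.kappa_fixed * p.delta * F_R
        growth = p.v_set * I_R - p.mu + p.alpha * qR

    if frozen_Q_R:
        # follow the seasonal driver: d(ln Q_R)/dt = Q_R'/Q_R
        dQR_driver = p.d_r * _TWO_PI / p.period * math.cos(_TWO_PI * t / p.period)
        dqR = dQR_driver / QR
    else:
        sigma = S / p.beta
        sgam = math.exp(p.gamma * lR) / (p.K_resource_dd**p.gamma)
        F_R = sigma / (1.0 + sigma + sgam)
        I_R = p.kappa_fixed * p.delta * F_R
        _, dqR = _qq_core(qR, I_R, p.v_set, p)

    dlR = growth - harvest
    return np.array([dlR, dqR, dx, dqX])


# --------------------------------------------------------------------------
# variant registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelVariant:
    """A variant bound to its log-coordinate vector field.

    ``rhs(t, y_log, u)`` returns the log-state derivative; ``x_index`` is the
    position of ln X in the log-state vector (used for extinction and
    switching events).
    """

    name: str
    state_names: tuple[str, ...]
    log_names: tuple[str, ...]
    rhs: object
    x_index: int

    def to_log(self, state) -> np.ndarray:
        return np.log(np.asarray(state, dtype=float))

    def from_log(self, y) -> np.ndarray:
        return np.exp(np.asarray(y, dtype=float))


VARIANT_NAMES = ("fixed", "cr3", "cr4")


def make_variant(
    name: str,
    p: ParameterSet,
    *,
    rho: float | None = None,
    logistic_resource: bool = False,
    frozen_Q_R: bool = False,
) -> ModelVariant:
    """Bind a named variant to a parameter set.

    For ``fixed``, ``rho`` is the constant background R/beta (defaults to the
    standard initial resource level 2e5 over beta).
    """
    if name == "fixed":
        rho_val = (2.0e5 / p.beta) if rho is None else float(rho)

        def rhs_fixed(t, y, u, _p=p, _rho=rho_val):
            return _rhs_fixed_log(t, y, u, _p, _rho)

        return ModelVariant(
            "fixed", ("X", "Q_X"), ("x", "q"), rhs_fixed, 0
        )
    if name == "cr3":

        def rhs_cr3(t, y, u, _p=p):
            return _rhs_cr3_log(t, y, u, _p)

        return ModelVariant(
            "cr3", ("R", "X", "Q_X"), ("ln_R", "x", "q"), rhs_cr3, 1
        )
    if name == "cr4":

        def rhs_cr4(t, y, u, _p=p, _lg=logistic_resource, _fz=frozen_Q_R):
            return _rhs_cr4_log(t, y, u, _p, _lg, _fz)

        return ModelVariant(
            "cr4",
            ("R", "Q_R", "X", "Q_X"),
            ("ln_R", "q_R", "x", "q"),
            rhs_cr4,
            2,
        )
    raise KeyError(f"unknown model variant {name!r}; choose from {VARIANT_NAMES}")
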