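"""Elementary rate functions shared by all model variants.

These are the building blocks of the right-hand sides: the
Beddington-DeAngelis-type extraction law with abrupt density dependence, the
sech allocation-efficiency penalty, the quality-dependent conversion
coefficient, and the seasonal drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ParameterSet

__all__ = [
    "feeding_rate",
    "allocation_efficiency",
    "resource_quality_conversion",
    "seasonal_drivers_eval",
    "DerivedRates",
    "derived_rates",
]


def feeding_rate(R: float, X: float, p: ParameterSet) -> float:
    """Per-capita intake f(R, X) * R of a consumer at abundance X on resource R.

    The extraction law is a Beddington-DeAngelis functional response with a
    shape parameter gamma controlling how abruptly intraspecific interference
    sets in around the abundance scale K:

        f(R, X) * R = delta * rho / (1 + rho + (X/K)**gamma),   rho = R / beta.

    It saturates at ``delta`` for abundant resources and a lone consumer,
    drops to ``delta/2`` at ``R = beta`` when ``X = 0``, increases with R and
    decreases with X.

    Parameters are taken from ``p``; negative inputs are rejected.
    """
    if R < 0 or X < 0:
        raise ValueError("R and X must be non-negative")
    if R == 0:
        return 0.0
    rho = R / p.beta
    return p.delta * rho / (1.0 + rho + (X / p.K_dd) ** p.gamma)


def allocation_efficiency(u: float, p: ParameterSet) -> float:
    """Conversion-efficiency multiplier sech(w * (u - v)).

    Equal to 1 at the physiological set point ``u = v`` (and everywhere when
    ``w = 0``), symmetric about ``v`` and strictly decreasing in ``|u - v|``
    for ``w > 0``.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("allocation proportion u must lie in [0, 1]")
    return 1.0 / math.cosh(p.w_cost * (u - p.v_set))


def resource_quality_conversion(Q_R: float, p: ParameterSet) -> float:
    """Conversion coefficient kappa(Q_R) = lam * Q_R**(1/(1+c_R)).

    Vanishes at Q_R = 0, reaches its maximum ``lam`` at Q_R = 1, is linear in
    Q_R for c_R = 0, and lies increasingly above the linear ramp as c_R grows
    (consumers extract a higher-than-average-quality fraction of the
    resource).
    """
    if not 0.0 <= Q_R <= 1.0:
        raise ValueError("Q_R must lie in [0, 1]")
    if Q_R == 0.0:
        return 0.0
    return p.lam * Q_R ** (1.0 / (1.0 + p.c_bias))


def seasonal_drivers_eval(t: float, p: ParameterSet) -> tuple[float, float]:
    """Seasonal carrying capacity S(t) and resource quality Q_R(t).

    S(t)   = S0 * (1 + 2 d_s sin(2 pi t / period))   (mean S0, positive for d_s <= 1/2)
    Q_R(t) = 0.5 + d_r sin(2 pi t / period)          (mean 0.5, in (0,1) for d_r < 1/2)

    Both collapse to their means when the amplitudes are zero.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = 2.0 * math.pi * t / p.period
    s = math.sin(w)
    return p.S0 * (1.0 + 2.0 * p.d_s * s), 0.5 + p.d_r * s


@dataclass(frozen=True)
class DerivedRates:
    """Per-state diagnostic rates evaluated along a trajectory.

    feeding    -- per-capita intake f(R,X)*R, in [0, delta]
    F_norm     -- normalised functional response f*R/delta, in [0, 1)
    I_rate     -- converted intake kappa_eff * f * R (1/month)
    theta      -- extrinsic decay theta = -alpha ln Q_X (>= 0)
    m_decay    -- total consumer decay mu + theta (>= mu)
    g_rate     -- net per-capita growth u*I - m_decay
    kappa_eff  -- conversion after quality and allocation-efficiency factors
    """

    feeding: float
    F_norm: float
    I_rate: float
    theta: float
    m_decay: float
    g_rate: float
    kappa_eff: float


def derived_rates(
    R: float, X: float, Q_X: float, Q_R: float, u: float, p: ParameterSet
) -> DerivedRates:
    """Evaluate the diagnostic rates at one state point."""
    fR = feeding_rate(R, X, p)
    kap = resource_quality_conversion(Q_R, p) * allocation_efficiency(u, p)
    I = kap * fR
    theta = -p.alpha * math.log(Q_X)
    m = p.mu + theta
    return DerivedRates(
        feeding=fR,
        F_norm=fR / p.delta if p.delta > 0 else 0.0,
        I_rate=I,
        theta=theta,
        m_decay=m,
        g_rate=u * I - m - p.eps_removal,
        kappa_eff=kap,
    )
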