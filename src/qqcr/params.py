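"""Model parameters for the quantity-quality (Q-Q) consumer-resource framework.

A single :class:`ParameterSet` record carries every rate and shape constant of
the three model variants (fixed-resource two-state, seasonal three-state
reduction, full four-state consumer-resource system).  All rates are per month;
biomass units are arbitrary but shared between consumer and resource.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Any, Mapping


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ParameterSet:
    """All rate/shape constants of the Q-Q consumer-resource models.

    Parameters
    ----------
    r : float
        Resource maximum per-capita growth rate (1/month).
    a : float
        Consumer quality response rate (1/month): scales how fast average
        quality responds to converted intake.
    d_s : float
        Relative amplitude of carrying-capacity forcing, ``0 <= d_s <= 0.5``.
        ``S(t) = S0 * (1 + 2 d_s sin(2 pi t / period))``; the bound keeps
        ``S(t) >= 0``.
    d_r : float
        Relative amplitude of resource-quality forcing, ``0 <= d_r < 0.5``.
        ``Q_R(t) = 0.5 + d_r sin(2 pi t / period)``; the bound keeps
        ``Q_R`` inside (0, 1).
    delta : float
        Maximum per-capita resource extraction rate (1/month).
    lam : float
        Maximum resource-to-consumer conversion coefficient, ``0 < lam < 1``.
    alpha : float
        Senescence-rate scale: extrinsic decay is ``theta = -alpha * ln Q_X``.
    mu : float
        Metabolic maintenance rate (1/month).
    beta : float
        Resource level at which extraction drops to half maximum in the
        absence of interference (biomass).
    gamma : float
        Abruptness of consumer density dependence, ``gamma >= 1``.
    K_dd : float
        Consumer abundance scale at which density dependence sets in (biomass).
    S0 : float
        Mean resource carrying capacity (biomass).
    c_bias : float
        Metabolism quality bias ``c``: metabolism preferentially burns
        higher-than-average-quality biomass, dragging quality down at rate
        ``c * mu``.  Also shapes the conversion curve kappa(Q_R).
    b_bias : float
        Senescence quality bias ``b``: senescence removes lower-than-average
        quality biomass, lifting quality at rate ``-b * alpha * ln Q_X``.
    v_set : float
        Physiological allocation set point ``v`` (the allocation proportion at
        which conversion efficiency is maximal), ``0 <= v < 1``.
    w_cost : float
        Efficiency-loss scale for deviations of the applied allocation ``u``
        from ``v``: conversion is multiplied by ``sech(w (u - v))``.
    eps_removal : float
        Extrinsic removal rate on the consumer (predation/harvest), default 0.
    kappa : float or None
        Base conversion coefficient for the fixed-resource variant.  ``None``
        (the default) resolves to ``kappa(Q_R = 0.5)`` of the coupled model so
        the variants are comparable.
    period : float
        Seasonal period in time units (12 months by default).
    """

    r: float = 0.5
    a: float = 0.1
    d_s: float = 0.0
    d_r: float = 0.0
    delta: float = 5.0
    lam: float = 0.2
    alpha: float = 0.1
    mu: float = 0.05
    beta: float = 30_000.0
    gamma: float = 2.0
    K_dd: float = 10_000.0
    S0: float = 1.0e6
    c_bias: float = 0.3
    b_bias: float = 0.05
    v_set: float = 0.5
    w_cost: float = 0.0
    eps_removal: float = 0.0
    kappa: float | None = None
    period: float = 12.0
    K_r_dd: float | None = None

    def __post_init__(self) -> None:
        _check(self.r >= 0, "r must be >= 0")
        _check(self.a >= 0, "a must be >= 0")
        _check(0 <= self.d_s <= 0.5, "d_s must lie in [0, 0.5]")
        _check(0 <= self.d_r < 0.5, "d_r must lie in [0, 0.5)")
        _check(self.delta >= 0, "delta must be >= 0")
        _check(0 < self.lam < 1, "lam must lie in (0, 1)")
        _check(self.alpha >= 0, "alpha must be >= 0")
        _check(self.mu >= 0, "mu must be >= 0")
        _check(self.beta > 0, "beta must be > 0")
        _check(self.gamma >= 1, "gamma must be >= 1")
        _check(self.K_dd > 0, "K_dd must be > 0")
        _check(self.S0 > 0, "S0 must be > 0")
        _check(self.c_bias >= 0, "c_bias must be >= 0")
        _check(self.b_bias >= 0, "b_bias must be >= 0")
        _check(0 <= self.v_set < 1, "v_set must lie in [0, 1)")
        _check(self.w_cost >= 0, "w_cost must be >= 0")
        _check(self.eps_removal >= 0, "eps_removal must be >= 0")
        _check(self.period > 0, "period must be > 0")
        if self.kappa is not None:
            _check(self.kappa > 0, "kappa must be > 0")
        if self.K_r_dd is not None:
            _check(self.K_r_dd > 0, "K_r_dd must be > 0")

    # -- derived quantities (never stored independently) -------------------

    @property
    def k_interference(self) -> float:
        """k = K^gamma, the interference normalisation of the extraction law."""
        return self.K_dd**self.gamma

    def rho(self, R: float) -> float:
        """Normalised resource level rho = R / beta."""
        return R / self.beta

    @property
    def kappa_fixed(self) -> float:
        """Conversion coefficient used by the fixed-resource variant.

        Defaults to kappa(Q_R = 0.5) = lam * 0.5**(1/(1+c)) so the
        fixed-resource and coupled variants agree when the resource quality
        driver sits at its mean.
        """
        if self.kappa is not None:
            return self.kappa
        return self.lam * 0.5 ** (1.0 / (1.0 + self.c_bias))

    @property
    def K_resource_dd(self) -> float:
        """Self-limitation scale of the resource in the four-state variant.

        Defaults to S0/6, which places the unharvested resource equilibrium
        near its mean carrying capacity.
        """
        return self.K_r_dd if self.K_r_dd is not None else self.S0 / 6.0

    # -- plumbing -----------------------------------------------------------

    def with_(self, **overrides: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))


def baseline() -> ParameterSet:
    """The baseline parameter set used throughout the numerical studies."""
    return ParameterSet()


#: Default initial conditions for the coupled variants (biomass, biomass, quality).
DEFAULT_INIT_CR = {"R": 2.0e5, "X": 1.0e4, "Q_X": 0.45, "Q_R": 0.5}
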