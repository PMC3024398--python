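"""Right-hand-side structure and cross-variant consistency."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qqcr import (
    StateCR3,
    StateCR4,
    StateQQ,
    find_equilibrium,
    rhs_fixed_resource,
    rhs_full_4d,
    rhs_seasonal_3d,
    simulate,
)

RHO = 20.0 / 3.0  # standard fixed background R(0)/beta


class TestFixedResourceRHS:
    def test_quality_decline_at_maximum_quality(self, p):
        # at q = 0 both quality source terms vanish: dq/dt = -c*mu
        _, dq = rhs_fixed_resource(StateQQ(x=9.0, q=0.0), 0.5, RHO, p)
        assert dq == pytest.approx(-p.c_bias * p.mu, abs=1e-15)
        assert dq == pytest.approx(-0.015, abs=1e-15)

    def test_full_allocation_kills_quality_intake(self, p):
        # at u = 1 the intake term (1-u) vanishes: dq is background-independent
        _, dq_rich = rhs_fixed_resource(StateQQ(9.0, -1.0), 1.0, 100.0, p)
        _, dq_poor = rhs_fixed_resource(StateQQ(9.0, -1.0), 1.0, 0.01, p)
        assert dq_rich == pytest.approx(dq_poor, abs=1e-15)

    def test_vanishes_at_equilibrium(self, p):
        eq = find_equilibrium("fixed", p, p.v_set, rho=RHO)
        assert eq.converged
        s = StateQQ(math.log(eq["X"]), math.log(eq["Q_X"]))
        dx, dq = rhs_fixed_resource(s, p.v_set, RHO, p)
        assert math.hypot(dx, dq) < 1e-8

    def test_rejects_positive_q(self):
        with pytest.raises(ValueError):
            StateQQ(1.0, 0.5)


class TestSeasonal3D:
    def test_no_harvest_without_consumers(self, p):
        pf = p.with_(d_s=0.3)
        s = StateCR3(R=2.0e5, X=0.0, Q_X=0.5)
        dR, dX, _ = rhs_seasonal_3d(s, 4.0, 0.5, pf)
        S = pf.S0 * (1.0 + 2 * 0.3 * math.sin(2 * math.pi * 4.0 / 12.0))
        assert dR == pytest.approx(pf.r * s.R * (1 - s.R / S), rel=1e-12)
        assert dX == 0.0

    def test_decay_is_mu_at_top_quality(self, p):
        # with u = 0 there is no growth term, so dX/X = -(mu - alpha ln Q_X)
        s = StateCR3(R=2.0e5, X=1.0e4, Q_X=1.0)
        _, dX, _ = rhs_seasonal_3d(s, 0.0, 0.0, p)
        assert dX / s.X == pytest.approx(-p.mu, abs=1e-12)

    def test_resource_loss_increases_with_consumers(self, p):
        # finite-difference check: d(dR/dt)/dX < 0 on interior states below
        # the interference turnover X* = K sqrt(1 + R/beta), beyond which
        # interference makes total harvest decline with consumer abundance
        for R in (1e5, 5e5, 9e5):
            for X in (1e3, 5e3, 1.5e4):
                d1 = rhs_seasonal_3d(StateCR3(R, X, 0.5), 0.0, 0.5, p)[0]
                d2 = rhs_seasonal_3d(StateCR3(R, X * 1.01, 0.5), 0.0, 0.5, p)[0]
                assert d2 < d1

    def test_harvest_conserves_flow_shape(self, p):
        # resource loss and consumer intake derive from the same f(R,X)
        s = StateCR3(R=3.0e5, X=2.0e4, Q_X=0.6)
        dR, _, _ = rhs_seasonal_3d(s, 0.0, 0.5, p)
        from qqcr import feeding_rate

        harvest = feeding_rate(s.R, s.X, p) / s.R * s.X * s.R  # f*X*R
        logistic = p.r * s.R * (1 - s.R / p.S0)
        assert dR == pytest.approx(logistic - harvest, rel=1e-12)


class TestFull4D:
    def test_reduces_to_3d_under_substitution(self, p):
        rng = np.random.default_rng(7)
        pf = p.with_(d_r=0.25, d_s=0.4)
        for _ in range(25):
            t = float(rng.uniform(0, 24))
            R = float(rng.uniform(1e4, 2e6))
            X = float(rng.uniform(10.0, 1e5))
            QX = float(rng.uniform(0.05, 1.0))
            u = float(rng.uniform(0, 1))
            _, QR_driver = (
                pf.S0 * (1 + 2 * pf.d_s * math.sin(2 * math.pi * t / 12)),
                0.5 + pf.d_r * math.sin(2 * math.pi * t / 12),
            )
            d4 = rhs_full_4d(
                StateCR4(R, QR_driver, X, QX), t, u, pf,
                logistic_resource=True, frozen_Q_R=True,
            )
            d3 = rhs_seasonal_3d(StateCR3(R, X, QX), t, u, pf)
            assert d4[0] == pytest.approx(d3[0], rel=1e-12, abs=1e-12)
            assert d4[2] == pytest.approx(d3[1], rel=1e-12, abs=1e-12)
            assert d4[3] == pytest.approx(d3[2], rel=1e-12, abs=1e-12)

    def test_consumer_terms_vanish_without_consumers(self, p):
        d = rhs_full_4d(StateCR4(2e5, 0.5, 0.0, 0.5), 0.0, 0.5, p)
        assert d[2] == 0.0

    def test_log_decay_terms_vanish_at_top_quality(self, p):
        # Q_R = Q_X = 1: both -ln Q contributions are zero
        d = rhs_full_4d(StateCR4(2e5, 1.0, 1e4, 1.0), 0.0, 0.0, p)
        assert d[2] / 1e4 == pytest.approx(-p.mu, abs=1e-12)


class TestTransformConsistency:
    def test_log_and_natural_integration_agree(self, p):
        """Integrating (x,q) in the package vs (X,Q) natural coordinates."""
        u, T = 0.55, 120.0
        traj = simulate("fixed", p, u, {"X": 1e4, "Q_X": 0.45}, (0.0, T), rho=RHO)

        def rhs_nat(t, y):
            X, Q = y
            s = StateQQ(math.log(X), math.log(Q))
            dx, dq = rhs_fixed_resource(s, u, RHO, p)
            return [X * dx, Q * dq]

        sol = solve_ivp(
            rhs_nat, (0.0, T), [1e4, 0.45], rtol=1e-10, atol=1e-12,
            t_eval=traj.times, method="LSODA",
        )
        assert np.allclose(sol.y[0], traj["X"], rtol=1e-6)
        assert np.allclose(sol.y[1], traj["Q_X"], rtol=1e-6)

    def test_set_point_irrelevant_without_cost(self, p):
        # with w = 0 the dynamics cannot depend on v
        t1 = simulate("cr3", p.with_(v_set=0.2), 0.5, None, (0.0, 60.0))
        t2 = simulate("cr3", p.with_(v_set=0.9), 0.5, None, (0.0, 60.0))
        assert np.array_equal(t1.states, t2.states)


class TestStateValidation:
    @pytest.mark.parametrize(
        "cls,kw",
        [
            (StateCR3, dict(R=-1.0, X=1.0, Q_X=0.5)),
            (StateCR3, dict(R=1.0, X=1.0, Q_X=1.5)),
            (StateCR4, dict(R=1.0, Q_R=0.0, X=1.0, Q_X=0.5)),
        ],
    )
    def test_domain_rejected(self, cls, kw):
        with pytest.raises(ValueError):
            cls(**kw)
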