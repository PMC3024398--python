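"""Equilibria, stability, period estimation, statistics, phase classification."""

import numpy as np
import pytest

from qqcr import (
    AllocationPolicy,
    classify_growth_phases,
    estimate_period,
    find_equilibrium,
    parameter_sweep,
    simulate,
    stability_spectrum,
    summary_stats,
)
from qqcr.analysis import _num_jacobian
from qqcr.models import ModelVariant


class TestFindEquilibrium:
    def test_fixed_baseline_interior(self, p):
        eq = find_equilibrium("fixed", p, p.v_set)
        assert eq.converged
        assert eq.residual < 1e-10
        assert eq.X > 1.0 and 0.0 < eq["Q_X"] < 1.0

    def test_boundary_has_no_interior_equilibrium(self, p):
        eq = find_equilibrium("fixed", p, 0.0)
        assert not eq.converged
        assert "boundary" in eq.message

    def test_agrees_with_long_simulation(self, p, fast_solver):
        eq = find_equilibrium("cr3", p, 0.5)
        traj = simulate("cr3", p, 0.5, None, (0.0, 900.0), fast_solver)
        assert eq.converged
        assert traj.X[-1] == pytest.approx(eq.X, rel=1e-3)


class TestStabilitySpectrum:
    def test_known_linear_spectrum(self):
        # decoupled linear system with rates -1 and -2
        mv = ModelVariant(
            "fixed", ("X", "Q_X"), ("x", "q"),
            lambda t, y, u: np.array([-1.0 * y[0], -2.0 * y[1]]), 0,
        )
        J = _num_jacobian(lambda y: mv.rhs(0.0, y, 0.5), np.array([0.3, -0.7]))
        ev = sorted(np.linalg.eigvals(J).real)
        assert ev == pytest.approx([-2.0, -1.0], abs=1e-8)

    def test_fixed_model_stable_across_allocations(self, p):
        """No oscillatory instability on a constant resource background."""
        for u in np.arange(0.2, 0.95, 0.1):
            st = stability_spectrum("fixed", p, float(u))
            assert st.stable, f"unstable at u={u}"

    def test_damped_approach_in_simulation(self, p, fast_solver):
        """Deviation extrema from equilibrium shrink monotonically."""
        eq = find_equilibrium("fixed", p, 0.5)
        traj = simulate(
            "fixed", p, 0.5, {"X": eq.X * 3.0, "Q_X": 0.9}, (0.0, 600.0), fast_solver
        )
        dev = np.abs(traj.X - eq.X)
        # local maxima of the deviation
        ext = [dev[i] for i in range(1, len(dev) - 1) if dev[i] >= dev[i - 1] and dev[i] >= dev[i + 1]]
        ext = [e for e in ext if e > 1e-6 * eq.X]
        assert all(b < a for a, b in zip(ext, ext[1:]))

    def test_jacobian_step_insensitivity(self, p):
        from qqcr.models import make_variant

        eq = find_equilibrium("fixed", p, 0.5)
        mv = make_variant("fixed", p)
        y0 = np.log(eq.state)
        J1 = _num_jacobian(lambda y: mv.rhs(0.0, y, 0.5), y0, h=1e-6)
        J2 = _num_jacobian(lambda y: mv.rhs(0.0, y, 0.5), y0, h=1e-5)
        assert np.allclose(np.linalg.eigvals(J1), np.linalg.eigvals(J2), rtol=1e-6)


class TestEstimatePeriod:
    def test_known_sinusoid(self, make_traj):
        t = np.arange(0.0, 1200.0, 1.0)
        X = 100.0 + 10.0 * np.sin(2 * np.pi * t / 60.0)
        est = estimate_period(make_traj(t, X), (0.0, 1200.0))
        assert est.period == pytest.approx(5.0, rel=0.02)
        assert est.spectral == pytest.approx(5.0, rel=0.1)

    def test_constant_yields_none(self, make_traj):
        t = np.arange(0.0, 600.0, 1.0)
        est = estimate_period(make_traj(t, np.full_like(t, 42.0)))
        assert est.period is None

    def test_too_few_peaks_yield_none(self, make_traj):
        t = np.arange(0.0, 100.0, 1.0)
        X = 100.0 + 10.0 * np.sin(2 * np.pi * t / 70.0)
        est = estimate_period(make_traj(t, X), (0.0, 100.0))
        assert est.period is None
        assert est.n_peaks < 3

    def test_scale_and_sampling_invariance(self, make_traj):
        t1 = np.arange(0.0, 2400.0, 1.0)
        t2 = np.arange(0.0, 2400.0, 0.5)
        make_X = lambda t: 50.0 + 20.0 * np.sin(2 * np.pi * t / 96.0)
        e1 = estimate_period(make_traj(t1, make_X(t1)), (0.0, 2400.0))
        e_scaled = estimate_period(make_traj(t1, 1e4 * make_X(t1)), (0.0, 2400.0))
        e_dense = estimate_period(make_traj(t2, make_X(t2)), (0.0, 2400.0))
        assert e_scaled.period == pytest.approx(e1.period, rel=1e-9)
        assert e_dense.period == pytest.approx(e1.period, rel=0.02)


class TestSummaryStats:
    def test_constant(self, make_traj):
        t = np.arange(0.0, 10.0, 0.5)
        st = summary_stats(make_traj(t, np.full_like(t, 7.0)))
        assert (st.min, st.max, st.mean, st.sigma) == (7.0, 7.0, 7.0, 0.0)

    def test_linear_ramp_mean(self, make_traj):
        t = np.linspace(0.0, 100.0, 1001)
        st = summary_stats(make_traj(t, np.linspace(0.0, 10.0, 1001)))
        assert st.mean == pytest.approx(5.0, abs=1e-9)

    def test_empty_window_rejected(self, make_traj):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            summary_stats(make_traj(t, t + 1.0), (50.0, 60.0))


class TestGrowthPhases:
    def test_pure_logistic_has_no_lag(self, make_traj):
        t = np.linspace(0.0, 300.0, 1501)
        X = 1e4 / (1.0 + (1e4 / 50.0 - 1.0) * np.exp(-0.05 * t))
        seg = classify_growth_phases(make_traj(t, X))
        labels = seg.labels()
        assert "lag" not in labels and "LogEx" not in labels
        for a, b in [("RegEx", "inhibition"), ("inhibition", "stationary")]:
            assert labels.index(a) < labels.index(b)

    def test_constant_is_stationary(self, make_traj):
        t = np.linspace(0.0, 100.0, 501)
        seg = classify_growth_phases(make_traj(t, np.full_like(t, 5.0)))
        assert seg.labels() == ["stationary"]

    def test_segments_contiguous_and_covering(self, make_traj):
        t = np.linspace(0.0, 300.0, 1501)
        X = 1e4 / (1.0 + (1e4 / 50.0 - 1.0) * np.exp(-0.05 * t))
        seg = classify_growth_phases(make_traj(t, X))
        assert seg.segments[0].t_start == t[0]
        assert seg.segments[-1].t_end == t[-1]
        for s1, s2 in zip(seg.segments, seg.segments[1:]):
            assert s1.t_end == pytest.approx(s2.t_start)

    def test_switching_culture_shows_lag_ending_at_threshold(self, p, fast_solver):
        """Quality-first allocation delays abundance growth until X_switch."""
        pp = p.with_(alpha=0.001, mu=0.01, c_bias=0.6, w_cost=1.0)
        pol = AllocationPolicy.threshold(0.07, 0.85, 1000.0, "quality_below")
        traj = simulate(
            "fixed", pp, pol, {"X": 100.0, "Q_X": 0.05}, (0.0, 600.0),
            fast_solver, rho=500_000.0 / 30_000.0,
        )
        seg = classify_growth_phases(traj)
        labels = seg.labels()
        assert "lag" in labels and "LogEx" in labels
        assert labels.index("lag") < labels.index("LogEx")
        lag_end = seg.segment("lag").t_end
        # the lag ends where the abundance crosses the switching threshold
        t_cross = traj.times[np.argmax(traj.X > 1000.0)]
        assert lag_end == pytest.approx(t_cross, abs=30.0)


class TestParameterSweep:
    def test_single_point_matches_direct_run(self, p, fast_solver):
        sw = parameter_sweep(
            "cr3", p, "r", [0.5], "mean", horizon=120.0, window=60.0, solver=fast_solver
        )
        traj = simulate("cr3", p, 0.5, None, (0.0, 120.0), fast_solver)
        st = summary_stats(traj, (60.0, 120.0))
        assert sw.metric[0] == pytest.approx(st.mean, rel=1e-9)

    def test_extinction_metric(self, p, fast_solver):
        sw = parameter_sweep(
            "cr3", p, "a", [0.0], "extinction", horizon=2400.0, solver=fast_solver
        )
        assert np.isfinite(sw.metric[0])
        assert sw.flags[0] == "extinct"
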