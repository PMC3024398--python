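"""Trajectory engine: policies, events, sliding, extinction, serialization."""

import numpy as np
import pytest

from qqcr import (
    AllocationPolicy,
    SolverSettings,
    evaluate_policy,
    simulate,
    summary_stats,
)


class TestPolicy:
    def test_constant(self):
        pol = AllocationPolicy.constant(0.3)
        assert evaluate_policy(5.0, pol) == 0.3

    def test_threshold_branches(self):
        pol = AllocationPolicy.threshold(0.0, 1.0, 4000.0, "grow_below")
        assert evaluate_policy(2000.0, pol) == 1.0
        assert evaluate_policy(8000.0, pol) == 0.0
        # the boundary belongs to the below branch
        assert evaluate_policy(4000.0, pol) == 1.0

    def test_quality_below_direction(self):
        pol = AllocationPolicy.threshold(0.07, 0.85, 1000.0, "quality_below")
        assert evaluate_policy(500.0, pol) == 0.07
        assert evaluate_policy(2000.0, pol) == 0.85

    @pytest.mark.parametrize(
        "kw",
        [
            dict(mode="constant", u_const=1.5),
            dict(mode="threshold", u_min=0.8, u_max=0.2),
            dict(mode="threshold", X_switch=-1.0),
            dict(mode="threshold", direction="sideways"),
            dict(mode="nonsense"),
        ],
    )
    def test_invalid_policies_rejected_at_construction(self, kw):
        with pytest.raises(ValueError):
            AllocationPolicy(**kw)


class TestSimulate:
    def test_zero_length_span(self, p):
        traj = simulate("cr3", p, 0.5, None, (0.0, 0.0))
        assert len(traj.times) == 1
        assert traj["X"][0] == pytest.approx(1e4)

    def test_deterministic(self, p, fast_solver):
        a = simulate("cr3", p, 0.5, None, (0.0, 120.0), fast_solver)
        b = simulate("cr3", p, 0.5, None, (0.0, 120.0), fast_solver)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.u, b.u)

    def test_baseline_equilibrates_without_oscillation(self, p, fast_solver):
        traj = simulate("cr3", p, 0.5, None, (0.0, 300.0), fast_solver)
        assert traj.extinct_at is None
        tail = traj.window(200.0, 300.0)
        rel_range = (tail.X.max() - tail.X.min()) / tail.X.mean()
        assert rel_range < 1e-2  # no oscillation in the final 100 months

    def test_zero_quality_response_goes_extinct(self, p, fast_solver):
        # with a = 0 quality decays toward 0 and the population collapses
        traj = simulate("cr3", p.with_(a=0.0), 0.5, None, (0.0, 2400.0), fast_solver)
        assert traj.extinct_at is not None
        # after extinction the reported abundance is 0
        assert np.all(traj.X[traj.times >= traj.extinct_at] == 0.0)

    def test_positivity_in_log_coordinates(self, p, fast_solver):
        pf = p.with_(d_r=0.45, d_s=0.45, delta=7.0)
        traj = simulate("cr3", pf, 0.5, None, (0.0, 600.0), fast_solver)
        alive = traj.X > 0
        assert np.all(traj["R"] > 0)
        assert np.all(traj["Q_X"] > 0) and np.all(traj["Q_X"] <= 1.0)
        assert np.all(np.isfinite(traj.states[alive]))

    def test_tolerance_refinement(self, p):
        """Halving solver tolerances moves the final abundance < 0.1%."""
        for variant, pp in [("cr3", p), ("cr3", p.with_(d_r=0.45, d_s=0.45)), ("fixed", p)]:
            base = simulate(variant, pp, 0.5, None, (0.0, 300.0),
                            SolverSettings(rtol=1e-8, atol=1e-10))
            fine = simulate(variant, pp, 0.5, None, (0.0, 300.0),
                            SolverSettings(rtol=5e-9, atol=5e-11))
            assert base.X[-1] == pytest.approx(fine.X[-1], rel=1e-3)


class TestSliding:
    def test_pinning_at_switch_level(self, p, fast_solver):
        """Strong forcing with full switching pins X at the threshold."""
        pf = p.with_(delta=7.0, d_r=0.45, d_s=0.45)
        pol = AllocationPolicy.threshold(0.0, 1.0, 4000.0, "grow_below")
        traj = simulate("cr3", pf, pol, None, (0.0, 360.0), fast_solver)
        assert traj.extinct_at is None
        st = summary_stats(traj, (240.0, 360.0))
        half_band = max(st.max - 4000.0, 4000.0 - st.min)
        assert half_band < 0.02 * 4000.0
        # the effective allocation on the surface is intermediate
        tail = traj.window(240.0, 360.0)
        assert np.any((tail.u > 0.05) & (tail.u < 0.95))

    def test_never_switching_when_threshold_unreachable(self, p, fast_solver):
        """X_switch above all attained abundances leaves u at its below value."""
        pf = p.with_(delta=7.0, d_r=0.45, d_s=0.45)
        pol = AllocationPolicy.threshold(0.0, 1.0, 2.0e6, "grow_below")
        traj = simulate("cr3", pf, pol, None, (0.0, 120.0), fast_solver)
        assert np.all(traj.u == 1.0)

    def test_chatter_mode_agrees_with_filippov(self, p):
        pf = p.with_(delta=7.0, d_r=0.45, d_s=0.45)
        pol = AllocationPolicy.threshold(0.0, 1.0, 4000.0, "grow_below")
        fil = simulate("cr3", pf, pol, None, (0.0, 48.0),
                       SolverSettings(rtol=1e-7, atol=1e-9))
        cha = simulate("cr3", pf, pol, None, (0.0, 48.0),
                       SolverSettings(sliding="chatter", chatter_dt=0.01))
        # both regulate to the same band once the surface is reached
        assert cha.X[-1] == pytest.approx(fil.X[-1], rel=0.02)


class TestTrajectoryIO:
    def test_csv_layout_and_json_echo(self, p, tmp_path, fast_solver):
        traj = simulate("cr3", p, 0.5, None, (0.0, 24.0), fast_solver)
        traj.save(tmp_path / "run")
        import json

        df_cols = (tmp_path / "run.csv").read_text().splitlines()[0]
        assert df_cols == "t,R,Q_R,X,Q_X,u,extinct"
        echo = json.loads((tmp_path / "run.json").read_text())
        assert echo["params"]["delta"] == 5.0
        assert echo["policy"]["mode"] == "constant"
        assert echo["variant"] == "cr3"

    def test_rerun_byte_identical(self, p, tmp_path, fast_solver):
        for name in ("a", "b"):
            simulate("cr3", p, 0.5, None, (0.0, 24.0), fast_solver).save(tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
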