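"""Turn segmentation, gate metrics and curvature estimation."""

import math

import numpy as np
import pytest

import sitski as sk
from sitski.analysis import (
    PATTERN_AFTER,
    PATTERN_AT,
    PATTERN_BEFORE,
    Trajectory,
    TurnSegment,
    curvature_profile,
    gate_metrics,
    segment_turns,
)
from sitski.simulate import Gate


def line_trajectory(y0: float = 1.34, speed: float = 10.0, n: int = 201) -> Trajectory:
    t = np.linspace(0.0, 10.0, n)
    return Trajectory(t=t, x=speed * t, y=np.full(n, y0))


class TestSegmentTurns:
    def test_constructed_crossings(self):
        """A sign change at t = 1.0 and 2.1 brackets a gate crossed at 1.6."""
        t = np.linspace(0.0, 3.0, 301)
        lean = np.where(t < 1.0, -5.0, np.where(t < 2.1, 5.0, -5.0))
        # crossing interpolation needs sign change between samples
        traj = Trajectory(t=t, x=10.0 * t, y=np.zeros_like(t), lean=lean)
        segs = segment_turns(traj, gates=[Gate("g", 16.0, 0.0, "left")])
        assert len(segs) == 1
        assert segs[0].t_start == pytest.approx(1.0, abs=0.02)
        assert segs[0].t_end == pytest.approx(2.1, abs=0.02)

    def test_all_positive_lean_single_segment(self):
        t = np.linspace(0.0, 3.0, 31)
        traj = Trajectory(t=t, x=10 * t, y=np.zeros_like(t), lean=np.full_like(t, 5.0))
        segs = segment_turns(traj, gates=[Gate("g", 15.0, 0.0, "left")])
        assert len(segs) == 1
        assert segs[0].t_start == t[0]
        assert segs[0].t_end == t[-1]

    def test_unreached_gate_skipped(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = Trajectory(t=t, x=10 * t, y=np.zeros_like(t), lean=np.full_like(t, 5.0))
        segs = segment_turns(traj, gates=[Gate("far", 99.0, 0.0, "left")])
        assert segs == []

    def test_missing_lean_errors(self):
        traj = line_trajectory()
        with pytest.raises(ValueError, match="lean"):
            segment_turns(traj, gates=[Gate("g", 50.0, 0.0, "left")])

    def test_simulator_segments_match_schedule_zeros(self, athlete, environment, course3):
        """Boundaries land on the control schedule's lean zero-crossings."""
        sched = sk.heuristic_schedule(course3, athlete, environment)
        res = sk.simulate_run(athlete, environment, course3.frame, course3, sched)
        traj = Trajectory.from_sim(res, frame=course3.frame)
        segs = segment_turns(traj, gates=list(course3.gates))
        assert len(segs) == len(course3.gates)
        # boundaries are zero-crossings of the recorded lean channel: the
        # samples bracketing each interior boundary change sign (or touch 0)
        for seg in segs:
            for tb in (seg.t_start, seg.t_end):
                if tb in (traj.t[0], traj.t[-1]):
                    continue
                i = int(np.searchsorted(traj.t, tb))
                assert traj.lean[max(i - 1, 0)] * traj.lean[min(i, len(traj) - 1)] <= 0


class TestGateMetrics:
    def segment_for(self, traj: Trajectory) -> TurnSegment:
        return TurnSegment("g", 0, len(traj), float(traj.t[0]), float(traj.t[-1]))

    def test_constant_offset_line(self):
        traj = line_trajectory(y0=1.34)
        gate = Gate("g", 50.0, 0.0, "right")
        m = gate_metrics(traj, gate, self.segment_for(traj))
        assert m.d_lev == pytest.approx(1.34, abs=1e-9)
        assert m.d_min == pytest.approx(1.34, abs=1e-9)
        assert m.pattern == PATTERN_AT
        assert m.L_s == pytest.approx(100.0, abs=1e-6)
        assert m.t_s == pytest.approx(10.0, abs=1e-12)

    def test_closest_approach_after_gate(self):
        """An arc whose apex sits past the gate level classifies as 'after'."""
        t = np.linspace(0.0, 2.0, 401)
        x = 10.0 * t
        apex_x = 12.0  # gate level at x=10, apex 0.2 s later
        y = 0.1 * (x - apex_x) ** 2 + 1.0
        traj = Trajectory(t=t, x=x, y=y)
        gate = Gate("g", 10.0, 0.0, "right")
        m = gate_metrics(traj, gate, self.segment_for(traj))
        assert m.pattern == PATTERN_AFTER

    def test_closest_approach_before_gate(self):
        t = np.linspace(0.0, 2.0, 401)
        x = 10.0 * t
        y = 0.1 * (x - 8.0) ** 2 + 1.0
        traj = Trajectory(t=t, x=x, y=y)
        m = gate_metrics(traj, Gate("g", 10.0, 0.0, "right"), self.segment_for(traj))
        assert m.pattern == PATTERN_BEFORE

    def test_continuous_minimum_vs_analytic_oracle(self):
        """Sparse-sample continuous d_min matches the exact line distance.

        For a diagonal path y = x the closest approach to the gate is the
        analytic point-to-line distance |x_g - y_g| / sqrt(2); a
        sample-only minimum would miss it by the sampling error.
        """
        t = np.linspace(0.0, 1.0, 51)
        traj = Trajectory(t=t, x=10 * t, y=10 * t)
        gate = Gate("g", 5.2, 4.1, "right")
        m = gate_metrics(traj, gate, self.segment_for(traj))
        exact = abs(gate.x - gate.y) / math.sqrt(2.0)
        assert m.d_min == pytest.approx(exact, abs=1e-6)
        sample_only = np.hypot(traj.x - gate.x, traj.y - gate.y).min()
        assert m.d_min <= sample_only

    def test_d_min_never_exceeds_d_lev(self, athlete, environment, course3):
        sched = sk.heuristic_schedule(course3, athlete, environment)
        res = sk.simulate_run(athlete, environment, course3.frame, course3, sched)
        traj = Trajectory.from_sim(res)
        for seg in segment_turns(traj, gates=list(course3.gates)):
            gate = next(g for g in course3.gates if g.id == seg.gate_id)
            m = gate_metrics(traj, gate, seg)
            assert m.d_min <= m.d_lev + 1e-9

    def test_pattern_antisymmetric_under_time_reversal(self):
        t = np.linspace(0.0, 2.0, 401)
        x = 10.0 * t
        y = 0.1 * (x - 12.0) ** 2 + 1.0
        traj = Trajectory(t=t, x=x, y=y)
        gate = Gate("g", 10.0, 0.0, "right")
        fwd = gate_metrics(traj, gate, self.segment_for(traj))
        rev_traj = traj.reversed()
        rev = gate_metrics(rev_traj, gate, self.segment_for(rev_traj))
        assert fwd.pattern == PATTERN_AFTER
        assert rev.pattern == PATTERN_BEFORE

    def test_gate_level_never_crossed_raises(self):
        traj = line_trajectory()
        seg = self.segment_for(traj)
        with pytest.raises(ValueError, match="far"):
            gate_metrics(traj, Gate("far", 900.0, 0.0, "right"), seg)

    def test_length_invariant_under_reparameterization(self):
        """L_s depends on the geometric path only; t_s does not."""
        t = np.linspace(0.0, 1.0, 101)
        x, y = 50 * t, np.sin(2 * np.pi * t)
        fast = Trajectory(t=t, x=x, y=y)
        slow = Trajectory(t=3 * t, x=x, y=y)
        gate = Gate("g", 25.0, 0.0, "right")
        seg_f = TurnSegment("g", 0, len(fast), 0.0, 1.0)
        seg_s = TurnSegment("g", 0, len(slow), 0.0, 3.0)
        mf = gate_metrics(fast, gate, seg_f)
        ms = gate_metrics(slow, gate, seg_s)
        assert mf.L_s == pytest.approx(ms.L_s, rel=1e-12)
        assert ms.t_s == pytest.approx(3 * mf.t_s, rel=1e-12)


class TestCurvature:
    def test_circle_quarter_arc(self):
        """100 points on a radius-5 circle recover R = 5.000 +/- 1e-3."""
        th = np.linspace(0.0, np.pi / 2, 100)
        traj = Trajectory(t=np.linspace(0, 1, 100), x=5 * np.cos(th), y=5 * np.sin(th))
        prof = curvature_profile(traj, window=3)
        interior = prof.radius[1:-1]
        assert np.all(np.abs(interior - 5.0) < 1e-3)

    def test_collinear_points_straight(self):
        traj = line_trajectory(n=50)
        prof = curvature_profile(traj, window=3)
        assert np.all(np.isinf(prof.radius))
        assert np.allclose(prof.kappa, 0.0)

    def test_ellipse_apex_curvature(self):
        """kappa at (a, 0) of an a=10, b=4 ellipse is a/b^2 = 0.625."""
        th = np.radians(np.arange(0.0, 360.0))
        traj = Trajectory(t=np.arange(360.0), x=10 * np.cos(th), y=4 * np.sin(th))
        prof = curvature_profile(traj, window=3)
        assert prof.kappa[0] == pytest.approx(0.625, rel=0.01)

    def test_scaling_property(self):
        """Scaling the path by c scales curvature by 1/c."""
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 1.0, 80)
        x = np.cumsum(rng.normal(1.0, 0.05, 80))
        y = np.sin(3 * t) + 0.1 * np.cumsum(rng.normal(0, 0.02, 80))
        base = curvature_profile(Trajectory(t=t, x=x, y=y), window=5)
        for c in (2.0, 5.0):
            scaled = curvature_profile(Trajectory(t=t, x=c * x, y=c * y), window=5)
            ok = base.kappa > 1e-4
            assert np.allclose(scaled.kappa[ok], base.kappa[ok] / c, rtol=1e-6)

    def test_duplicate_points_deduplicated(self, caplog):
        t = np.linspace(0, 1, 40)
        x = np.repeat(np.linspace(0, 10, 20), 2)
        y = np.zeros(40)
        prof = curvature_profile(Trajectory(t=t, x=x, y=y), window=3)
        assert prof.kappa.size == 20

    @pytest.mark.parametrize("window", [2, 1, 4])
    def test_window_validation(self, window):
        traj = line_trajectory()
        with pytest.raises(ValueError):
            curvature_profile(traj, window=window)

    def test_wider_window_on_noisy_arc(self):
        """A wider window stabilizes radii on a noisy constant-radius arc."""
        rng = np.random.default_rng(7)
        th = np.linspace(0.0, np.pi / 2, 300)
        x = 20 * np.cos(th) + rng.normal(0, 0.01, 300)
        y = 20 * np.sin(th) + rng.normal(0, 0.01, 300)
        traj = Trajectory(t=np.linspace(0, 3, 300), x=x, y=y)
        wide = curvature_profile(traj, window=11)
        med = np.median(wide.radius[np.isfinite(wide.radius)])
        assert med == pytest.approx(20.0, rel=0.25)


class TestTrajectoryContainer:
    def test_strictly_increasing_time_required(self):
        with pytest.raises(ValueError):
            Trajectory(t=[0.0, 0.0, 1.0], x=[0, 1, 2], y=[0, 0, 0])

    def test_resample_preserves_endpoints(self):
        traj = line_trajectory(n=101)
        res = traj.resample(7.0)
        assert res.t[0] == traj.t[0]
        assert np.interp(res.t[-1], traj.t, traj.x) == pytest.approx(res.x[-1])

    def test_dataframe_round_trip(self):
        traj = line_trajectory(n=11)
        back = Trajectory.from_dataframe(traj.to_dataframe())
        assert np.array_equal(back.t, traj.t)
        assert np.array_equal(back.x, traj.x)
        assert back.lean is None
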