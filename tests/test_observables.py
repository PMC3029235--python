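"""Metric extraction from trajectories: exactness, floors, robustness."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagosim.errors import InputError
from phagosim.observables import (
    compare_trace,
    engulfment_time,
    max_inward_speed,
    push_out_distance,
    summarize,
)
from tests.conftest import make_linear_trace


class TestExactOnFixtures:
    def test_programmed_peak_recovered(self, linear_trace):
        assert push_out_distance(linear_trace) == pytest.approx(1.0, abs=1e-12)

    def test_programmed_completion_recovered(self, linear_trace):
        assert engulfment_time(linear_trace) == pytest.approx(150.0, abs=1e-9)

    def test_programmed_inward_speed_recovered(self, linear_trace):
        assert max_inward_speed(linear_trace) == pytest.approx(33.0, rel=1e-9)

    @settings(max_examples=15, deadline=None)
    @given(
        st.floats(0.2, 2.0),
        st.floats(20.0, 60.0),
        st.floats(100.0, 250.0),
        st.floats(10.0, 80.0),
    )
    def test_arbitrary_programmed_fixtures(self, d, t_peak, T, v_nm):
        tr = make_linear_trace(d_star=d, t_peak=t_peak, T_star=T, v_star_nm=v_nm)
        assert push_out_distance(tr) == pytest.approx(d, abs=1e-9)
        assert engulfment_time(tr) == pytest.approx(T, abs=1e-6)
        assert max_inward_speed(tr) == pytest.approx(v_nm, rel=1e-6)


class TestEdgeCases:
    def test_monotone_inward_trace_floors_at_zero(self):
        tr = make_linear_trace(d_star=0.0, t_peak=1e-6)
        tr.target_position = -0.02 * tr.time
        assert push_out_distance(tr) == 0.0

    def test_threshold_zero_gives_zero_time(self, linear_trace):
        assert engulfment_time(linear_trace, completion_threshold=0.0) == 0.0

    def test_incomplete_run_returns_marker(self, linear_trace):
        assert engulfment_time(linear_trace, completion_threshold=0.999) is None

    def test_constant_position_zero_speed(self):
        tr = make_linear_trace()
        tr.target_position = np.full_like(tr.time, 2.0)
        assert max_inward_speed(tr) == 0.0

    def test_fraction_step_fixture(self):
        tr = make_linear_trace()
        tr.engulfed_fraction = np.where(tr.time >= 66.0, 1.0, 1e-9)
        assert engulfment_time(tr) == pytest.approx(66.0)

    def test_short_trace_rejected(self):
        tr = make_linear_trace()
        tr.time = tr.time[:4]
        tr.target_position = tr.target_position[:4]
        tr.engulfed_fraction = tr.engulfed_fraction[:4]
        with pytest.raises(InputError):
            max_inward_speed(tr)


class TestWindowRobustness:
    def test_speed_stable_under_window_doubling(self, linear_trace):
        v1 = max_inward_speed(linear_trace, window=5.0)
        v2 = max_inward_speed(linear_trace, window=10.0)
        assert abs(v1 - v2) / v1 < 0.10


class _BenchView:
    def __init__(self, traj):
        self.time = traj.time
        self.position = traj.target_position
        self.engulfed_fraction = traj.engulfed_fraction


class TestCompare:
    def test_self_comparison_zero_rms(self, linear_trace):
        out = compare_trace(linear_trace, _BenchView(linear_trace))
        assert out["rms_um"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_does_not_bias_displacement_rms(self, linear_trace):
        import copy

        shifted = copy.deepcopy(linear_trace)
        shifted.target_position = shifted.target_position + 0.7
        # displacements from contact are compared, so a constant offset in
        # absolute position cancels
        out = compare_trace(linear_trace, _BenchView(shifted))
        assert out["rms_um"] == pytest.approx(0.0, abs=1e-12)

    def test_no_overlap_rejected(self, linear_trace):
        import copy

        other = copy.deepcopy(linear_trace)
        other.time = other.time + 1e6
        with pytest.raises(InputError):
            compare_trace(linear_trace, _BenchView(other))

    def test_summary_bundle(self, linear_trace):
        s = summarize(linear_trace)
        assert s.complete
        assert s.push_out_distance == pytest.approx(1.0)
        assert s.time_of_peak == pytest.approx(30.0)
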