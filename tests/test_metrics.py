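import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taxikit as tk
from taxikit.metrics import (
    BinSeries,
    NormalizationSpec,
    binseries_to_frame,
    pooled_sine_summary,
)

from conftest import make_track


def static_cells_trackset(rhos, duration=600.0):
    """One static track per radial distance, placed on the +x axis."""
    tracks = []
    for i, rho in enumerate(rhos):
        times = np.arange(0.0, duration + 1)
        tracks.append(make_track(f"c{i}", times, np.full(times.size, float(rho)),
                                 np.zeros(times.size)))
    return tk.TrackSet(tracks=tuple(tracks))


class TestFrameBinCounts:
    def test_snapshot_binning(self, geometry):
        ts = static_cells_trackset([50, 150, 400])
        counts = tk.frame_bin_counts(ts, geometry, 60.0)
        assert [s.values[0] for s in counts] == [1, 1, 0]

    def test_boundary_cell_in_outer_ring(self, geometry):
        ts = static_cells_trackset([224.0])
        counts = tk.frame_bin_counts(ts, geometry, 60.0)
        assert counts[2].values[0] == 1  # 224 = 2*112 opens ring C

    def test_sixty_second_grid_has_eleven_points(self, geometry):
        ts = static_cells_trackset([100.0], duration=600.0)
        counts = tk.frame_bin_counts(ts, geometry, 60.0)
        assert counts[0].times.size == 11
        assert counts[0].times[-1] == 600.0

    def test_interval_must_be_frame_multiple(self, geometry):
        ts = static_cells_trackset([100.0])
        with pytest.raises(ValueError, match="multiple"):
            tk.frame_bin_counts(ts, geometry, 60.5)

    def test_counts_never_exceed_live_tracks(self, geometry, assay_simulations):
        ts = assay_simulations["control"]
        counts = tk.frame_bin_counts(ts, geometry, 60.0)
        totals = np.sum([s.values for s in counts], axis=0)
        assert np.all(totals <= len(ts))


class TestNormalizeCounts:
    def _series(self, values, times=None):
        values = np.asarray(values, dtype=float)
        times = np.arange(values.size) * 60.0 if times is None else times
        return BinSeries(bin=0, metric="count", times=times, values=values,
                         n_contributing=values.astype(int), label="A")

    def test_z_score_with_baseline_subtraction(self):
        out = tk.normalize_counts([self._series([2, 4, 6])], NormalizationSpec())[0]
        np.testing.assert_allclose(out.values, [0.0, 1.2247, 2.4495], atol=1e-4)

    def test_constant_series_guarded_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = tk.normalize_counts([self._series([5, 5, 5])])[0]
        np.testing.assert_array_equal(out.values, 0.0)

    def test_baseline_point_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        out = tk.normalize_counts([self._series(rng.integers(1, 30, 11))])[0]
        assert out.values[0] == 0.0

    def test_missing_baseline_time_rejected(self):
        series = self._series([1, 2, 3], times=np.array([30.0, 60.0, 90.0]))
        with pytest.raises(ValueError, match="baseline"):
            tk.normalize_counts([series], NormalizationSpec(baseline_time=0.0))

    @given(a=st.floats(min_value=0.1, max_value=50), b=st.floats(min_value=-20, max_value=20))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_under_affine_rescaling(self, a, b):
        raw = np.array([3.0, 9.0, 1.0, 7.0, 5.0])
        base = tk.normalize_counts([self._series(raw)])[0]
        scaled = tk.normalize_counts([self._series(a * raw + b)])[0]
        np.testing.assert_allclose(base.values, scaled.values, atol=1e-9)

    def test_replicates_pool_within_ring(self):
        rep1 = self._series([2, 4, 6])
        rep2 = self._series([4, 6, 8])
        out = tk.normalize_counts([rep1, rep2])
        pooled = np.array([2, 4, 6, 4, 6, 8], dtype=float)
        sigma = pooled.std()
        np.testing.assert_allclose(out[0].values, (np.array([2, 4, 6]) - 2) / sigma,
                                   atol=1e-12)


class TestStepSineAngle:
    def test_radial_approach_is_plus_one(self):
        assert tk.step_sine_angle((100, 0), (90, 0), (0, 0)) == pytest.approx(1.0)

    def test_radial_retreat_is_minus_one(self):
        assert tk.step_sine_angle((100, 0), (110, 0), (0, 0)) == pytest.approx(-1.0)

    def test_tangential_step_geometry(self):
        val = tk.step_sine_angle((100, 0), (100, 10), (0, 0))
        assert val == pytest.approx((100 - math.hypot(100, 10)) / 10, rel=1e-9)
        assert val == pytest.approx(-0.0499, abs=1e-4)

    def test_zero_length_step_missing(self):
        assert math.isnan(tk.step_sine_angle((5, 5), (5, 5), (0, 0)))

    @given(
        x1=st.floats(-300, 300), y1=st.floats(-300, 300),
        x2=st.floats(-300, 300), y2=st.floats(-300, 300),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_antisymmetric(self, x1, y1, x2, y2):
        if (x1, y1) == (x2, y2):
            return
        fwd = tk.step_sine_angle((x1, y1), (x2, y2), (0, 0))
        rev = tk.step_sine_angle((x2, y2), (x1, y1), (0, 0))
        assert -1.0 - 1e-12 <= fwd <= 1.0 + 1e-12
        assert fwd == pytest.approx(-rev, abs=1e-9)


class TestBinnedMeanSine:
    def test_all_inward_steppers_average_plus_one(self, geometry):
        times = np.arange(0.0, 61.0)
        inward1 = make_track("i1", times, 100.0 - 0.5 * times, np.zeros(times.size))
        inward2 = make_track("i2", times, np.zeros(times.size), 90.0 - 0.4 * times)
        ts = tk.TrackSet(tracks=(inward1, inward2))
        sine = tk.binned_mean_sine(ts, geometry, 60.0)
        assert sine[0].values[0] == pytest.approx(1.0)

    def test_single_track_window_missing(self, geometry):
        times = np.arange(0.0, 61.0)
        only = make_track("solo", times, 100.0 - 0.5 * times, np.zeros(times.size))
        far = make_track("far", times, 300.0 - 0.5 * times, np.zeros(times.size))
        ts = tk.TrackSet(tracks=(only, far))
        sine = tk.binned_mean_sine(ts, geometry, 60.0)
        assert math.isnan(sine[0].values[0])

    def test_null_walkers_pooled_mean_near_zero(self, null_trackset, geometry):
        mean, se = pooled_sine_summary(null_trackset, geometry)
        assert abs(mean) < 3 * se


class TestSumDistance:
    def test_summation(self, geometry):
        ts = static_cells_trackset([50, 70])
        sd = tk.sum_distance_series(ts, geometry, 60.0)
        assert sd[0].values[0] == pytest.approx(120.0)

    def test_static_cells_give_constant_series(self, geometry):
        ts = static_cells_trackset([50, 70, 150, 300])
        for s in tk.sum_distance_series(ts, geometry, 60.0):
            assert np.ptp(s.values) == pytest.approx(0.0)

    def test_total_includes_all_rings(self, geometry):
        ts = static_cells_trackset([50, 150, 260])
        total = tk.total_sum_distance(ts, geometry, 60.0)
        assert total.values[0] == pytest.approx(460.0)

    def test_attractant_total_trend_negative(self, geometry, assay_simulations):
        total = tk.total_sum_distance(assay_simulations["attractant"], geometry,
                                      include_outside=True)
        assert tk.trend_slope(total).slope < 0


class TestTrendSlope:
    def test_exact_line(self):
        t = np.arange(0.0, 11.0)
        res = tk.trend_slope((t, 100.0 - 2.0 * t))
        assert res.slope == pytest.approx(-2.0)
        assert res.stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_series(self):
        t = np.arange(0.0, 11.0)
        res = tk.trend_slope((t, np.full(11, 7.0)))
        assert res.slope == pytest.approx(0.0)

    def test_three_point_line(self):
        res = tk.trend_slope((np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0])))
        assert res.slope == pytest.approx(1.0)
        assert res.stderr == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            tk.trend_slope((np.array([0.0, 1.0]), np.array([0.0, 1.0])))

    def test_missing_values_dropped(self):
        t = np.arange(0.0, 6.0)
        y = np.array([0.0, 1.0, math.nan, 3.0, 4.0, 5.0])
        res = tk.trend_slope((t, y))
        assert res.slope == pytest.approx(1.0)


class TestTidyExport:
    def test_long_format_columns(self, geometry):
        ts = static_cells_trackset([50, 150])
        frame = binseries_to_frame(tk.frame_bin_counts(ts, geometry, 60.0))
        assert list(frame.columns) == ["bin", "label", "metric", "time_s", "value", "n"]
        assert set(frame["label"]) == {"A", "B", "C"}
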