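import math

import numpy as np
import pytest

import taxikit as tk
from taxikit.kinetics import TaylorFit

from conftest import make_track


class TestRmsNetDisplacement:
    def test_ballistic_identity(self, straight_track):
        ts = tk.TrackSet(tracks=(straight_track,))
        series = tk.rms_net_displacement(ts, time_grid=np.array([1.0, 10.0, 100.0]))
        np.testing.assert_allclose(series.rms, [2.0, 20.0, 200.0])

    def test_rms_of_two_tracks(self):
        # net distances 3 and 4 at t=10 -> sqrt((9+16)/2)
        a = make_track("a", [0, 10], [0, 3], [0, 0])
        b = make_track("b", [0, 10], [0, 0], [0, 4])
        ts = tk.TrackSet(tracks=(a, b))
        series = tk.rms_net_displacement(ts, time_grid=np.array([10.0]))
        assert series.rms[0] == pytest.approx(math.sqrt(12.5), rel=1e-12)
        assert series.rms[0] == pytest.approx(3.536, abs=5e-4)

    def test_short_tracks_excluded_beyond_their_span(self):
        short = make_track("short", np.arange(0, 301, 50), np.arange(7) * 10, np.zeros(7))
        long = make_track("long", np.arange(0, 601, 50), np.arange(13) * 10, np.zeros(13))
        ts = tk.TrackSet(tracks=(short, long))
        series = tk.rms_net_displacement(ts, time_grid=np.array([200.0, 400.0]))
        np.testing.assert_array_equal(series.n_tracks_at_t, [2, 1])

    def test_empty_trackset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tk.rms_net_displacement(tk.TrackSet(tracks=()))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        times = np.arange(20.0)
        xy = np.cumsum(rng.normal(0, 2, size=(20, 2)), axis=0)
        angle = 1.1
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = xy @ rot.T + [55.0, -20.0]
        ts_a = tk.TrackSet(tracks=(make_track("a", times, xy[:, 0], xy[:, 1]),))
        ts_b = tk.TrackSet(tracks=(make_track("a", times, moved[:, 0], moved[:, 1]),))
        ra = tk.rms_net_displacement(ts_a)
        rb = tk.rms_net_displacement(ts_b)
        np.testing.assert_allclose(ra.rms, rb.rms, rtol=1e-9)


class TestTaylorModel:
    def test_ballistic_limit(self):
        """rms -> v*t for t << tau."""
        v, tau = 1.7, 50.0
        t = np.array([0.001, 0.01, 0.05])
        np.testing.assert_allclose(tk.taylor_rms(t, v, tau), v * t, rtol=1e-3)

    def test_diffusive_limit(self):
        """rms^2 -> 4Dt with D = v^2 tau/2 for t >> tau."""
        v, tau = 1.7, 2.0
        d = v**2 * tau / 2
        t = np.array([2e3, 2e4])
        np.testing.assert_allclose(tk.taylor_rms(t, v, tau) ** 2, 4 * d * t, rtol=2e-3)


class TestFitTaylor:
    def test_noiseless_self_consistency(self):
        t = np.arange(1.0, 601.0)
        series = tk.RmsSeries(times=t, rms=tk.taylor_rms(t, 2.0, 10.0),
                              n_tracks_at_t=np.full(t.size, 50))
        fit = tk.fit_taylor(series)
        assert fit.v == pytest.approx(2.0, rel=1e-4)
        assert fit.tau == pytest.approx(10.0, rel=1e-4)
        assert fit.converged and fit.identifiable

    def test_purely_ballistic_flagged_non_identifiable(self):
        t = np.arange(1.0, 601.0)
        series = tk.RmsSeries(times=t, rms=2.0 * t, n_tracks_at_t=np.full(t.size, 10))
        fit = tk.fit_taylor(series)
        assert not fit.identifiable
        assert fit.v == pytest.approx(2.0, rel=0.01)

    def test_recovery_on_simulated_tracks(self, null_trackset):
        """v from the fit tracks the realized mean step speed within 10%."""
        series = tk.rms_net_displacement(null_trackset, estimator="all_lag")
        fit = tk.fit_taylor(series)
        realized = np.concatenate(
            [tk.step_speeds(trk)[1] for trk in null_trackset]
        ).mean()
        assert fit.v == pytest.approx(realized, rel=0.10)

    def test_too_few_points_rejected(self):
        series = tk.RmsSeries(times=np.arange(1.0, 5.0), rms=np.arange(1.0, 5.0),
                              n_tracks_at_t=np.full(4, 5))
        with pytest.raises(ValueError, match="5 time points"):
            tk.fit_taylor(series)


class TestDeriveMotilityParams:
    def test_defining_identities_at_machine_precision(self):
        fit = tk.derive_motility_params(TaylorFit(v=1.6067, tau=14.85), bead_radius=50.0)
        assert fit.lam == fit.v * fit.tau
        assert fit.D == fit.v**2 * fit.tau / 2
        assert fit.beta == 4 * math.pi * 50.0 * fit.D

    def test_treatment_column_lambda(self):
        # v chosen so that v*tau reproduces the treatment decorrelation length
        fit = tk.derive_motility_params(TaylorFit(v=23.86 / 14.85, tau=14.85))
        assert fit.lam == pytest.approx(23.86, abs=5e-3)

    def test_treatment_column_diffusivity(self):
        fit = tk.derive_motility_params(TaylorFit(v=23.86 / 14.85, tau=14.85))
        assert fit.D == pytest.approx(19.17, abs=5e-3)

    def test_encounter_kernel_arithmetic(self):
        fit = tk.derive_motility_params(TaylorFit(v=23.86 / 14.85, tau=14.85),
                                        bead_radius=50.0)
        assert fit.beta == pytest.approx(4 * math.pi * 50.0 * 19.17, rel=1e-3)
        assert fit.beta == pytest.approx(1.204e4, rel=1e-3)

    def test_planar_dimensionality_validated_by_control_column(self):
        """lambda^2/(n*tau) reproduces the control diffusivity only for n=2."""
        lam, tau = 10.70, 4.68
        d_n2 = lam**2 / (2 * tau)
        d_n3 = lam**2 / (3 * tau)
        assert d_n2 == pytest.approx(12.22, abs=0.02)
        assert abs(d_n3 - 12.22) > 4.0

    def test_negative_bead_radius_rejected(self):
        with pytest.raises(ValueError):
            tk.derive_motility_params(TaylorFit(v=1.0, tau=1.0), bead_radius=-1.0)


class TestCompareMotility:
    @pytest.fixture
    def printed_fits(self):
        control = TaylorFit(v=10.70 / 4.68, tau=4.68, lam=10.70, D=12.22, beta=8200.0)
        treatment = TaylorFit(v=23.86 / 14.85, tau=14.85, lam=23.86, D=19.17, beta=14900.0)
        return control, treatment

    def test_diffusivity_percent_increase(self, printed_fits):
        table = tk.compare_motility(*printed_fits)
        d_pct = table.set_index("parameter").loc["D", "percent_change"]
        assert d_pct == pytest.approx(56.9, abs=0.05)
        assert round(d_pct) == 57

    def test_encounter_kernel_percent_increase(self, printed_fits):
        table = tk.compare_motility(*printed_fits)
        b_pct = table.set_index("parameter").loc["beta", "percent_change"]
        assert b_pct == pytest.approx(81.7, abs=0.05)

    def test_identical_fits_give_zeros(self, printed_fits):
        control, _ = printed_fits
        table = tk.compare_motility(control, control)
        np.testing.assert_allclose(table["percent_change"], 0.0)

    def test_zero_reference_flagged(self):
        a = TaylorFit(v=0.0, tau=1.0)
        b = TaylorFit(v=1.0, tau=1.0)
        table = tk.compare_motility(a, b).set_index("parameter")
        assert math.isnan(table.loc["v", "percent_change"])


class TestBinnedMeanSpeed:
    def test_two_cell_window_mean(self, geometry):
        # both cells in bin A, speeds 1 and 3 um/s
        a = make_track("a", np.arange(31.0), 10 + np.arange(31.0), np.zeros(31))
        b = make_track("b", np.arange(31.0), 10 + 3 * np.arange(31.0), np.full(31, 5.0))
        ts = tk.TrackSet(tracks=(a, b))
        raw, logged = tk.binned_mean_speed(ts, geometry, window_s=30.0)
        assert raw[0].values[0] == pytest.approx(2.0)
        assert logged[0].values[0] == pytest.approx(
            (math.log(2.0) + math.log(4.0)) / 2
        )

    def test_single_track_window_missing(self, geometry):
        a = make_track("a", np.arange(31.0), 10 + np.arange(31.0), np.zeros(31))
        far = make_track("far", np.arange(31.0), 400 + np.arange(31.0), np.zeros(31))
        ts = tk.TrackSet(tracks=(a, far))
        raw, _ = tk.binned_mean_speed(ts, geometry, window_s=30.0)
        assert math.isnan(raw[0].values[0])  # only track "a" contributes to bin A

    def test_empty_window_missing(self, geometry):
        a = make_track("a", np.arange(31.0), 10 + np.arange(31.0), np.zeros(31))
        b = make_track("b", np.arange(31.0), 15 + np.arange(31.0), np.zeros(31))
        ts = tk.TrackSet(tracks=(a, b))
        raw, _ = tk.binned_mean_speed(ts, geometry, window_s=30.0)
        assert math.isnan(raw[2].values[0])  # nobody ever visits bin C


class TestMotileFraction:
    def test_all_static(self):
        pos = np.zeros((10, 2))
        assert tk.motile_fraction(pos, pos, tolerance_um=1.0) == 0.0

    def test_counting(self):
        a = np.zeros((3, 2))
        b = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 12.0]])
        assert tk.motile_fraction(a, b, tolerance_um=1.0) == pytest.approx(2 / 3)

    def test_infinite_tolerance(self):
        a = np.zeros((5, 2))
        b = np.random.default_rng(0).uniform(-100, 100, (5, 2))
        assert tk.motile_fraction(a, b, tolerance_um=math.inf) == 0.0

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            tk.motile_fraction(np.zeros((3, 2)), np.zeros((4, 2)))
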