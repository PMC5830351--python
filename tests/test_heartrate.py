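import numpy as np
import pytest

from condyn.design import CS_MINUS, generate_design
from condyn.heartrate import (RRSeries, deceleration_response, hr_dynamics,
                              instantaneous_hr, read_rr, trial_hr_curves,
                              weighted_bin)
from condyn.synth import acquisition_truth, simulate_rr


class TestInstantaneousHr:
    def test_one_second_intervals_give_60_bpm(self):
        rate = instantaneous_hr(RRSeries.from_intervals(np.full(20, 1.0)))
        assert np.all(rate(np.linspace(0.1, 19.9, 50)) == 60.0)

    def test_half_second_interval_gives_120_bpm(self):
        rate = instantaneous_hr(RRSeries.from_intervals(np.full(20, 0.5)))
        assert rate(1.0) == 120.0

    def test_alternating_intervals_give_step_function(self):
        iv = np.tile([0.5, 1.0], 10)
        rate = instantaneous_hr(RRSeries.from_intervals(iv))
        # first interval [0, 0.5) at 120, second [0.5, 1.5) at 60, ...
        assert rate(0.25) == 120.0
        assert rate(1.0) == 60.0
        assert rate(1.75) == 120.0

    def test_artifact_interval_interpolated_with_warning(self):
        iv = np.full(20, 1.0)
        iv[10] = 5.0  # outside the physiological guard
        with pytest.warns(UserWarning, match="guard"):
            rate = instantaneous_hr(RRSeries.from_intervals(iv))
        mid = np.sum(iv[:10]) + 2.5
        assert rate(mid) == pytest.approx(60.0)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            RRSeries(beat_times=np.array([1.0]))
        with pytest.raises(ValueError):
            RRSeries(beat_times=np.array([1.0, 1.0, 2.0]))


class TestWeightedBin:
    def test_constant_rate_fills_every_bin(self):
        rate = instantaneous_hr(RRSeries.from_intervals(np.full(60, 1.0)))
        np.testing.assert_allclose(weighted_bin(rate, 10.0), 60.0)

    def test_half_and_half_bin_averages(self):
        """First half of a bin at 60 bpm, second half at 120 → 90 bpm."""
        times = np.array([0.0, 0.5, 0.75, 1.0, 1.25, 1.5])
        from condyn.heartrate import StepRate
        rate = StepRate(times=times, rates=np.array([60.0, 120, 120, 120, 120]))
        out = weighted_bin(rate, 0.5, window=(-0.5, 0.5), bin_s=1.0)
        assert out[0] == pytest.approx(90.0)

    def test_bin_inside_one_interval_returns_its_rate(self):
        rate = instantaneous_hr(RRSeries.from_intervals(np.full(10, 2.0)))
        out = weighted_bin(rate, 5.0, window=(0.0, 1.0), bin_s=1.0)
        assert out[0] == 30.0

    def test_window_beyond_recording_rejected(self):
        rate = instantaneous_hr(RRSeries.from_intervals(np.full(5, 1.0)))
        with pytest.raises(ValueError, match="beyond"):
            weighted_bin(rate, 4.5)

    def test_matches_millisecond_integration_on_random_step_functions(self):
        """Exactness oracle: with interval knots on the 1-ms grid, the
        weighted bin equals dense left-sampled integration to 1e-9."""
        rng = np.random.default_rng(0)
        for rep in range(10):
            iv = np.round(rng.uniform(0.4, 1.4, size=200), 3)
            rr = RRSeries.from_intervals(iv)
            rate = instantaneous_hr(rr)
            onset = float(np.round(rng.uniform(10, 100), 3))
            bins = weighted_bin(rate, onset)
            dt = 1e-3
            for j in range(6):
                a = onset - 1.0 + j
                t = a + dt * np.arange(int(round(1.0 / dt)))
                dense = rate(t + dt / 2).mean()
                assert abs(bins[j] - dense) < 1e-9 * max(abs(dense), 1.0)

    def test_binning_conserves_time(self):
        """Interval overlaps within each bin sum to the bin width."""
        rng = np.random.default_rng(1)
        iv = rng.uniform(0.5, 1.2, size=100)
        rr = RRSeries.from_intervals(iv)
        rate = instantaneous_hr(rr)
        ones = rate.__class__(times=rate.times, rates=np.ones_like(rate.rates))
        np.testing.assert_allclose(weighted_bin(ones, 30.0), 1.0, atol=1e-12)


class TestTrialCurves:
    def test_constant_rate_gives_zero_change(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=2)
        rr = RRSeries.from_intervals(np.full(200, 1.0))
        m = trial_hr_curves(rr, d)
        np.testing.assert_allclose(m.change, 0.0, atol=1e-12)
        assert m.values.shape == (10, 6)

    def test_paired_trials_excluded(self):
        d = generate_design(seed=3)
        truth = acquisition_truth(seed=3)
        truth.hr_noise_sd_bpm = 0.0
        rr = simulate_rr(d, truth, seed=4)
        m = trial_hr_curves(rr, d)
        assert len(m.conditions) == 102

    def test_planted_deceleration_recovered_noise_free(self):
        """A narrow 5-bpm CS+ bump at 2.5 s (CS− none) appears as ≈ −5 bpm
        in the 2–3 s bin of the CS+ minus CS− change curves."""
        d = generate_design(pairing_rate=0.0, n_initial_paired=0, seed=5)
        truth = acquisition_truth(n_trials=120, hr_amp_cs_plus_bpm=5.0,
                                  hr_amp_cs_minus_bpm=0.0, seed=5)
        truth.hr_noise_sd_bpm = 0.0
        truth.hr_width_s = 0.8
        truth.hr_diff_shape = None  # constant deceleration across trials
        rr = simulate_rr(d, truth, baseline_bpm=70.0, seed=6)
        m = trial_hr_curves(rr, d)
        plus = m.change[m.conditions != CS_MINUS].mean(axis=0)
        minus = m.change[m.conditions == CS_MINUS].mean(axis=0)
        diff = plus - minus
        # analytic mean of the Gaussian bump over the 2-3 s bin; the beat-level
        # sampling (piecewise-constant HR at ~0.86-s resolution) smooths a
        # bump of comparable width, so ~10% attenuation is expected
        from scipy.stats import norm
        expected = -5.0 * 0.8 * np.sqrt(2 * np.pi) * (
            norm.cdf(3.0, 2.5, 0.8) - norm.cdf(2.0, 2.5, 0.8))
        assert diff[3] == pytest.approx(expected, abs=0.6)
        assert abs(diff[3] + 5.0) < 1.1  # ballpark of the planted amplitude

    def test_label_shuffle_removes_difference(self):
        d = generate_design(pairing_rate=0.0, n_initial_paired=0, seed=7)
        truth = acquisition_truth(hr_amp_cs_plus_bpm=5.0,
                                  hr_amp_cs_minus_bpm=0.0, seed=7)
        truth.hr_noise_sd_bpm = 0.0
        truth.hr_diff_shape = None
        rr = simulate_rr(d, truth, seed=8)
        m = trial_hr_curves(rr, d)
        rng = np.random.default_rng(9)
        shuffled = rng.permutation(m.conditions)
        real = (m.change[m.conditions != CS_MINUS].mean(axis=0)
                - m.change[m.conditions == CS_MINUS].mean(axis=0))
        fake = (m.change[shuffled != CS_MINUS].mean(axis=0)
                - m.change[shuffled == CS_MINUS].mean(axis=0))
        assert np.abs(fake).max() < 0.25 * np.abs(real).max()

    def test_baseline_offset_cancels_in_change(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=10)
        for bpm in (50.0, 90.0):
            rr = RRSeries.from_intervals(np.full(300, 60.0 / bpm))
            m = trial_hr_curves(rr, d)
            np.testing.assert_allclose(m.change, 0.0, atol=1e-9)


class TestHrDynamics:
    def test_declining_difference_yields_negative_slope(self):
        """HR difference decaying over trials: smoothed differential declines."""
        from condyn.dynamics import adaptation_slope
        d = generate_design(pairing_rate=0.0, n_initial_paired=0, seed=11)
        truth = acquisition_truth(hr_amp_cs_plus_bpm=6.0,
                                  hr_amp_cs_minus_bpm=1.0, change_point=40,
                                  seed=11)
        truth.hr_noise_sd_bpm = 0.0
        rr = simulate_rr(d, truth, seed=12)
        out = hr_dynamics(trial_hr_curves(rr, d))
        # deceleration is negative, so a shrinking difference rises toward 0
        assert out["split"].differential["early"] < out["split"].differential["late"]
        assert adaptation_slope(out["differential"]) > 0
        assert out["mean_difference_bpm"] < 0

    def test_deceleration_window_must_overlap_bins(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=13)
        rr = RRSeries.from_intervals(np.full(300, 1.0))
        m = trial_hr_curves(rr, d)
        with pytest.raises(ValueError):
            deceleration_response(m, decel_window_s=(10.0, 11.0))


def test_rr_file_round_trip(tmp_path):
    iv = np.random.default_rng(14).uniform(0.6, 1.1, size=50)
    path = tmp_path / "rr.txt"
    np.savetxt(path, iv, fmt="%.6f")
    rr = read_rr(path)
    np.testing.assert_allclose(rr.intervals_s, iv, atol=1e-6)


class TestSimulateRr:
    def test_constant_rate_gives_unit_intervals(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=15)
        truth = acquisition_truth(n_trials=10, hr_amp_cs_plus_bpm=0.0,
                                  hr_amp_cs_minus_bpm=0.0, seed=15)
        truth.hr_noise_sd_bpm = 0.0
        rr = simulate_rr(d, truth, baseline_bpm=60.0, seed=16)
        np.testing.assert_allclose(rr.intervals_s, 1.0, atol=1e-9)

    def test_same_seed_identical_series(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=17)
        truth = acquisition_truth(n_trials=10, seed=17)
        a = simulate_rr(d, truth, seed=18)
        b = simulate_rr(d, truth, seed=18)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_excessive_amplitude_rejected(self):
        d = generate_design(n_trials=10, pairing_rate=0.0, n_initial_paired=0,
                            seed=19)
        truth = acquisition_truth(n_trials=10, hr_amp_cs_plus_bpm=80.0, seed=19)
        with pytest.raises(ValueError, match="amplitude"):
            simulate_rr(d, truth, baseline_bpm=70.0, seed=20)
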