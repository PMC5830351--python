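import numpy as np
import pytest

from condyn.design import CS_MINUS, CS_PLUS_UNPAIRED
from condyn.dynamics import (TrialSeries, adaptation_slope, differential_curve,
                             early_late_test, raw_contrast_series,
                             smooth_curves, smoothing_sensitivity,
                             split_early_late, to_trial_series)


def make_series(values_plus, values_minus, spacing=5.6, start=10.0):
    """Alternating CS+/CS− series with regular onsets."""
    n = len(values_plus) + len(values_minus)
    onsets = start + spacing * np.arange(n)
    conditions = np.array([CS_PLUS_UNPAIRED, CS_MINUS] * (n // 2))
    values = np.empty(n)
    values[0::2] = values_plus
    values[1::2] = values_minus
    return TrialSeries(onsets=onsets, conditions=conditions, values=values)


class TestSplitEarlyLate:
    def test_boundary_is_open_closed(self):
        """Onset 335.9 s is early; 336.0 s is late (t < 5.6 min)."""
        onsets = np.array([10.0, 20.0, 335.9, 336.0, 500.0, 510.0])
        conds = np.array([CS_PLUS_UNPAIRED, CS_MINUS, CS_PLUS_UNPAIRED,
                          CS_MINUS, CS_PLUS_UNPAIRED, CS_MINUS])
        s = TrialSeries(onsets, conds, np.arange(6.0))
        split = split_early_late(s)
        assert split.counts[("early", CS_PLUS_UNPAIRED)] == 2
        assert split.counts[("late", CS_MINUS)] == 2

    def test_partition_covers_all_trials(self, noiseless_beta):
        split = split_early_late(noiseless_beta)
        total = sum(split.counts.values())
        assert total == noiseless_beta.analysis_mask().sum()

    def test_identical_amplitudes_give_zero_differential(self):
        s = make_series(np.full(30, 2.0), np.full(30, 2.0))
        split = split_early_late(s, t_split_s=10 + 5.6 * 30)
        assert split.differential["early"] == pytest.approx(0.0)
        assert split.differential["late"] == pytest.approx(0.0)

    def test_planted_decline_early_exceeds_late(self, noiseless_beta):
        """Differential 1.0 declining to 0 after trial 60 of 120."""
        split = split_early_late(noiseless_beta)
        assert split.differential["early"] > split.differential["late"]
        assert split.differential["early"] == pytest.approx(1.0, abs=1e-6)

    def test_empty_cell_raises_with_names(self):
        s = make_series(np.ones(4), np.ones(4))
        with pytest.raises(ValueError, match="late"):
            split_early_late(s, t_split_s=1e6)


class TestEarlyLateTest:
    def test_identical_periods_give_t_zero_p_one(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        out = early_late_test(x, x.copy())
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_benjamini_hochberg_hand_example(self):
        """BH on p = (0.01, 0.02, 0.04) adjusts to (0.03, 0.03, 0.04)."""
        from condyn._stats import fdr_bh
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            early_late_test(np.ones((1, 3)), np.zeros((1, 3)))


class TestSmoothing:
    def test_constant_series_is_reproduced(self):
        s = make_series(np.full(20, 3.0), np.full(20, 3.0))
        c = smooth_curves(s, bandwidth_trials=4)
        np.testing.assert_allclose(c.cs_plus, 3.0)
        np.testing.assert_allclose(c.cs_minus, 3.0)

    def test_large_bandwidth_approaches_condition_mean(self):
        rng = np.random.default_rng(5)
        vp, vm = rng.normal(size=20), rng.normal(size=20)
        s = make_series(vp, vm)
        c = smooth_curves(s, bandwidth_trials=1e4)
        np.testing.assert_allclose(c.cs_plus, vp.mean(), atol=1e-6)
        np.testing.assert_allclose(c.cs_minus, vm.mean(), atol=1e-6)

    def test_step_series_tracked_away_from_edge(self):
        """A 2-level step is followed within 5% away from the jump and the
        block edges, at a small bandwidth."""
        vp = np.concatenate([np.full(20, 10.0), np.full(20, 5.0)])
        s = make_series(vp, np.zeros(40))
        c = smooth_curves(s, bandwidth_trials=1.0)
        plus_at, _ = c.evaluate(c.plus_onsets)
        assert np.all(np.abs(plus_at[5:15] - 10.0) < 0.5)
        assert np.all(np.abs(plus_at[25:35] - 5.0) < 0.25)

    def test_smoother_is_linear(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = make_series(np.zeros(20), np.zeros(20))
        sx = make_series(x, np.zeros(20))
        sy = make_series(y, np.zeros(20))
        sxy = make_series(2 * x + 3 * y, np.zeros(20))
        cx = smooth_curves(sx, 3).cs_plus
        cy = smooth_curves(sy, 3).cs_plus
        cxy = smooth_curves(sxy, 3).cs_plus
        np.testing.assert_allclose(cxy, 2 * cx + 3 * cy, atol=1e-10)

    def test_too_few_trials_rejected(self):
        s = make_series(np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            smooth_curves(s)


class TestDifferentialCurve:
    def test_identical_curves_give_zeros(self):
        s = make_series(np.full(20, 1.5), np.full(20, 1.5))
        d = differential_curve(smooth_curves(s, 4))
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(d.trial_values, 0.0, atol=1e-12)

    def test_contrast_series_length_matches_cs_plus_trials(self, noiseless_beta):
        s = to_trial_series(noiseless_beta)
        d = differential_curve(smooth_curves(s))
        assert len(d.trial_values) == (s.conditions == CS_PLUS_UNPAIRED).sum()

    def test_constant_shift_cancels_exactly(self):
        """Adding the same constant to every trial's value leaves the
        differential curve untouched."""
        rng = np.random.default_rng(7)
        vp, vm = rng.normal(size=20), rng.normal(size=20)
        d0 = differential_curve(smooth_curves(make_series(vp, vm), 4))
        d1 = differential_curve(smooth_curves(make_series(vp + 5, vm + 5), 4))
        np.testing.assert_allclose(d1.values, d0.values, atol=1e-10)
        np.testing.assert_allclose(d1.trial_values, d0.trial_values, atol=1e-10)

    def test_slow_drift_nearly_cancels(self):
        """A linear condition-independent drift leaks only marginally into
        the differential (the two conditions sample it at different onsets)."""
        rng = np.random.default_rng(8)
        vp, vm = rng.normal(size=30), rng.normal(size=30)
        s0 = make_series(vp, vm)
        drift = 0.05 * s0.onsets  # 0.05 units/s, ~17 units over the block
        s1 = make_series(vp + drift[0::2], vm + drift[1::2])
        d0 = differential_curve(smooth_curves(s0, 4))
        d1 = differential_curve(smooth_curves(s1, 4))
        leak = np.abs(d1.trial_values - d0.trial_values).max()
        assert leak < 0.05 * np.abs(drift).max()

    def test_habituation_block_fluctuates_around_zero(self):
        """With no planted difference, the differential stays near zero."""
        rng = np.random.default_rng(9)
        s = make_series(rng.normal(0, 0.3, 30), rng.normal(0, 0.3, 30))
        d = differential_curve(smooth_curves(s, 5))
        assert abs(d.values.mean()) < 0.3


class TestAdaptationSlope:
    def test_flat_curve_has_zero_slope(self):
        s = make_series(np.full(20, 2.0), np.zeros(20))
        assert adaptation_slope(differential_curve(smooth_curves(s, 2))) == \
            pytest.approx(0.0, abs=1e-10)

    def test_exact_line_recovered(self):
        d = differential_curve(smooth_curves(make_series(np.ones(20),
                                                         np.zeros(20)), 3))
        d.trial_values = -0.01 * np.arange(1, 21)
        assert adaptation_slope(d) == pytest.approx(-0.01)

    def test_planted_decline_gives_negative_group_slope(self):
        """18 noisy subjects with a planted declining difference: group mean
        slope negative and significant (one-sample t)."""
        from scipy import stats
        rng = np.random.default_rng(10)
        slopes = []
        for _ in range(18):
            diff = np.concatenate([np.full(15, 1.0), np.linspace(1, 0, 15)])
            vp = diff + rng.normal(0, 0.5, 30)
            vm = rng.normal(0, 0.5, 30)
            s = make_series(vp, vm)
            slopes.append(adaptation_slope(differential_curve(smooth_curves(s, 5))))
        t, p = stats.ttest_1samp(slopes, 0.0)
        assert np.mean(slopes) < 0 and t < 0 and p < 0.05

    def test_sensitivity_runs_at_three_bandwidths(self, noiseless_beta):
        out = smoothing_sensitivity(to_trial_series(noiseless_beta))
        assert list(out["bandwidth_trials"]) == [3.0, 5.0, 8.0]
        assert (out["slope"] < 0).all()


def test_raw_contrast_series_matches_smoothed_on_smooth_data(noiseless_beta):
    """On noise-free data the raw-contrast option agrees with the smoothed
    contrasts up to the smoothing bias of the CS+ curve."""
    s = to_trial_series(noiseless_beta)
    raw = raw_contrast_series(s)
    smoothed = differential_curve(smooth_curves(s)).trial_values
    assert np.corrcoef(raw, smoothed)[0, 1] > 0.95
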