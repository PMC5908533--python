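"""Skewness, subthreshold distance, firing rates and Fano factors."""

import numpy as np
import pytest

from wavepatch.stats import (
    fano_factor,
    firing_rate,
    mean_matched_fano,
    skewness,
    spike_counts,
    subthreshold_distance,
    trial_statistic_summary,
)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sample_approaches_two(self):
        # moment skewness of Exp(1) is exactly 2
        rng = np.random.default_rng(0)
        s = skewness(rng.exponential(1.0, size=2_000_000))
        assert s == pytest.approx(2.0, abs=0.05)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(skewness(np.full(10, 3.0)))

    def test_sign_agrees_with_mean_minus_median(self):
        rng = np.random.default_rng(1)
        for sample in (
            rng.exponential(1.0, 5000),        # right-tailed
            -rng.exponential(1.0, 5000),       # left-tailed
            rng.lognormal(0.0, 0.8, 5000),     # right-tailed
        ):
            s = skewness(sample)
            assert np.sign(s) == np.sign(np.mean(sample) - np.median(sample))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            skewness(np.array([1.0, 2.0]))


class TestSubthresholdDistance:
    def test_constant_trace_arithmetic(self):
        v = np.full(100, -66.0)
        assert subthreshold_distance(v, v_th=-55.0) == pytest.approx(11.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            subthreshold_distance(np.empty(0), v_th=-55.0)

    def test_trial_summary_median_then_mean(self):
        per_trial = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        summ = trial_statistic_summary(per_trial)
        np.testing.assert_allclose(summ.median_across_trials, [2.0, 20.0])
        assert summ.mean == pytest.approx(11.0)


class TestFiringRate:
    def test_poisson_train_recovers_rate(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 100_000, size=rng.poisson(9.0 * 100)))
        times, rate = firing_rate(t, 0.0, 100_000.0, window_ms=250.0)
        assert rate.mean() == pytest.approx(9.0, rel=0.1)

    def test_empty_spike_train_zero_rate(self):
        _, rate = firing_rate(np.array([]), 0.0, 1000.0)
        assert np.all(rate == 0.0)

    def test_window_boundaries_half_open(self):
        t = np.array([250.0, 500.0])
        _, counts = spike_counts([t], 0.0, 500.0, window_ms=250.0, stride_ms=250.0)
        # windows (0,250] and (250,500]: one spike each
        np.testing.assert_array_equal(counts[0], [1.0, 1.0])


class TestFanoFactor:
    def test_identical_counts_give_zero(self):
        counts = np.tile([3.0, 5.0, 2.0], (10, 1))
        np.testing.assert_allclose(fano_factor(counts), 0.0)

    def test_poisson_counts_near_one_at_500_trials(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(500, 40)).astype(float)
        ff = fano_factor(counts)
        assert 0.9 <= ff.mean() <= 1.1

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            fano_factor(np.ones((1, 5)))

    def test_rate_switching_inflates_ff_with_window(self):
        # doubly stochastic counts: two-state rate switching across trials
        rng = np.random.default_rng(4)
        ffs = []
        for window_s in (0.1, 0.4):
            rates = rng.choice([3.0, 30.0], size=(400, 1))
            counts = rng.poisson(rates * window_s, size=(400, 30)).astype(float)
            ffs.append(np.nanmean(fano_factor(counts)))
        assert ffs[0] > 1.0
        assert ffs[1] > ffs[0]


class TestMeanMatchedFano:
    def test_identical_mean_distribution_matches_raw(self):
        # every neuron keeps the same mean at every window: nothing discarded
        rng = np.random.default_rng(5)
        counts = rng.poisson(5.0, size=(30, 100, 6)).astype(float)
        res = mean_matched_fano(counts, n_resamples=10, seed=6)
        assert res.mean_matched
        np.testing.assert_allclose(res.mm_ff, res.raw_ff, atol=0.06)

    def test_matching_removes_rate_artifact(self):
        # rate doubles at the later windows for half the neurons; matching
        # keeps the FF estimate driven by count dispersion, not rate
        rng = np.random.default_rng(7)
        lam = np.full((40, 1, 8), 4.0)
        lam[:20, :, 4:] = 8.0
        counts = rng.poisson(np.broadcast_to(lam, (40, 200, 8))).astype(float)
        res = mean_matched_fano(counts, n_resamples=20, seed=8)
        assert res.mean_matched
        assert np.nanmax(np.abs(res.mm_ff - 1.0)) < 0.15  # Poisson stays ~1

    def test_matched_histogram_never_exceeds_any_window(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(rng.uniform(1, 10, size=(25, 1, 5)),
                             size=(25, 80, 5)).astype(float)
        means = counts.mean(axis=1)
        edges = np.histogram_bin_edges(means, bins=20)
        hists = np.stack([np.histogram(means[:, w], bins=edges)[0] for w in range(5)])
        common = hists.min(axis=0)
        assert np.all(common <= hists)  # floor-histogram dominance

    def test_needs_multiple_windows(self):
        with pytest.raises(ValueError):
            mean_matched_fano(np.ones((5, 10, 1)))
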