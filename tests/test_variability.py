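"""Shared variance, ISI-CV and Fano factor with their matching rules."""

import numpy as np
import pytest

from statecode import variability as vb
from statecode.variability import FaDecomposition


class TestFactorAnalysis:
    def test_independent_units_share_little_variance(self):
        rng = np.random.default_rng(0)
        counts = rng.normal(5, 1, size=(15, 2000))
        fa = vb.fit_factor_analysis(counts, m_grid=(1, 2, 3), seed=0)
        assert np.nanmean(vb.shared_variance_per_unit(fa)) < 5.0

    def test_one_factor_ground_truth_recovered(self):
        rng = np.random.default_rng(1)
        n_units, n_bins = 12, 8000
        load = rng.uniform(0.8, 1.5, n_units)
        psi = rng.uniform(0.5, 1.5, n_units)
        z = rng.standard_normal(n_bins)
        counts = np.outer(load, z) + rng.standard_normal((n_units, n_bins)) * np.sqrt(psi)[:, None]
        fa = vb.fit_factor_analysis(counts, m_grid=(1, 2), seed=1)
        expected = 100 * load**2 / (load**2 + psi)
        got = vb.shared_variance_per_unit(fa)
        assert np.abs(got - expected).max() < 5.0

    def test_model_covariance_matches_sample_covariance(self):
        rng = np.random.default_rng(2)
        n_units, n_bins = 10, 10_000
        L = rng.normal(size=(n_units, 2))
        x = L @ rng.standard_normal((2, n_bins)) + rng.standard_normal((n_units, n_bins))
        fa = vb.fit_factor_analysis(x, m_grid=(2,), seed=2)
        model_cov = fa.loadings @ fa.loadings.T + np.diag(fa.psi)
        sample_cov = np.cov(x)
        rel = np.linalg.norm(model_cov - sample_cov) / np.linalg.norm(sample_cov)
        assert rel < 0.15

    def test_constant_units_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        counts = rng.normal(size=(5, 500))
        counts[2] = 7.0
        with pytest.warns(RuntimeWarning, match="constant"):
            fa = vb.fit_factor_analysis(counts, m_grid=(1,), seed=0)
        assert 2 not in fa.kept_units


class TestPercentSharedVariance:
    @pytest.mark.parametrize(
        "load,psi,expected",
        [
            (np.sqrt([3.0]), 1.0, 75.0),
            ([0.0], 2.0, 0.0),
            ([1.3], 0.0, 100.0),
        ],
    )
    def test_formula_arithmetic(self, load, psi, expected):
        fa = FaDecomposition(
            mean=np.zeros(1),
            loadings=np.atleast_2d(np.asarray(load, float)),
            psi=np.array([psi]),
            m=1,
        )
        assert vb.percent_shared_variance(fa, 0) == pytest.approx(expected)

    def test_degenerate_unit_reported_missing(self):
        fa = FaDecomposition(np.zeros(1), np.zeros((1, 1)), np.zeros(1), 1)
        assert np.isnan(vb.percent_shared_variance(fa, 0))

    def test_bounded_and_monotone_in_loading(self):
        vals = []
        for l2 in (0.5, 1.0, 2.0, 4.0):
            fa = FaDecomposition(np.zeros(1), np.array([[np.sqrt(l2)]]), np.ones(1), 1)
            v = vb.percent_shared_variance(fa, 0)
            assert 0.0 <= v <= 100.0
            vals.append(v)
        assert np.all(np.diff(vals) > 0)


class TestIsiCv:
    def test_periodic_train_cv_exactly_zero(self):
        assert vb.isi_cv(np.arange(0, 100, 0.25)) == 0.0

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(4)
        train = np.cumsum(rng.exponential(1 / 5.0, size=4000))  # ~800 s at 5 spk/s
        assert abs(vb.isi_cv(train, cap=2.5) - 1.0) < 0.05

    def test_cap_discards_long_intervals(self):
        train = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        isis_kept = np.array([0.1, 0.1, 0.1, 0.1])  # the 9.8 s gap is dropped
        assert vb.isi_cv(train) == pytest.approx(isis_kept.std(ddof=1) / isis_kept.mean())

    def test_too_few_spikes_missing(self):
        assert np.isnan(vb.isi_cv(np.array([0.1, 0.5])))

    def test_state_mask_restricts_spikes(self):
        mask = np.zeros(100, bool)
        mask[:50] = True  # first 1.5 s only
        train = np.concatenate([np.arange(0, 1.5, 0.05), np.arange(1.5, 3.0, 0.001)])
        cv_masked = vb.isi_cv(train, state_mask=mask)
        assert cv_masked == pytest.approx(0.0, abs=1e-9)


class TestFanoFactor:
    def test_identical_counts_zero(self):
        ff, n = vb.fano_factor(np.full((20, 10), 4.0))
        assert ff == 0.0 and n == 10

    def test_poisson_counts_near_one(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.5, size=(100, 200)).astype(float)
        ff, _ = vb.fano_factor(counts)
        assert abs(ff - 1.0) < 0.05

    def test_negative_binomial_overdispersion(self):
        rng = np.random.default_rng(6)
        counts = rng.negative_binomial(3, 0.5, size=(300, 60)).astype(float)  # mean 3
        ff, _ = vb.fano_factor(counts)
        assert abs(ff - 2.0) < 0.1  # 1 + mu / r

    def test_min_trial_rule(self):
        counts = np.ones((12, 4))
        ws = np.full((12, 4), -1)
        ws[:9, 0] = 0  # only 9 trials in state 0 for window 0
        ff, n = vb.fano_factor(counts, ws, state=0, min_trials=10)
        assert np.isnan(ff) and n == 0

    def test_window_state_labels_strict(self):
        labels = np.array([0] * 5 + [1] * 5 + [1] * 3 + [0] * 2)  # 3 windows of 5 bins
        out = vb.window_state_labels(labels, window_s=0.15, bin_s=0.03)
        assert out.tolist() == [0, 1, -1]

    def test_gaze_conditioning_neutral_when_rates_gaze_independent(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(2.0, size=(60, 80)).astype(float)
        gaze = rng.integers(0, 2, 60)
        ff_all, _ = vb.fano_factor(counts)
        ff_gaze, _ = vb.fano_factor(counts, gaze_cluster_ids=gaze)
        assert abs(ff_all - ff_gaze) < 0.1

    def test_gaze_cluster_count(self):
        rng = np.random.default_rng(8)
        xy = np.vstack([rng.normal(c, 0.2, size=(20, 2)) for c in range(5)])
        ids = vb.gaze_clusters(xy, n_clusters=5)
        assert np.unique(ids).size == 5


class TestStateMatching:
    def test_matched_equals_unmatched_when_already_matched(self):
        rng = np.random.default_rng(9)
        n_units, n_bins = 8, 3000
        z = rng.standard_normal(n_bins)
        counts = np.outer(np.ones(n_units), z) + rng.standard_normal((n_units, n_bins))
        labels = np.repeat([0, 1], n_bins // 2)
        matched = vb.state_matched_shared_variance(
            counts, labels, m_grid=(1,), n_boot=3, seed=0
        )
        plain = []
        for s in (0, 1):
            fa = vb.fit_factor_analysis(counts[:, labels == s], m_grid=(1,), seed=0)
            plain.append(vb.shared_variance_per_unit(fa))
        assert np.abs(matched - np.array(plain)).max() < 10.0

    def test_thinning_preserves_poisson_fano(self):
        rng = np.random.default_rng(10)
        train = np.cumsum(rng.exponential(1 / 20.0, size=20_000))
        thinned = vb.thin_spikes(train, 0.5, rng)
        counts = vb.bin_counts(thinned, thinned[-1], window_s=0.15)
        ff = counts.var(ddof=1) / counts.mean()
        assert abs(ff - 1.0) < 0.1
        assert abs(thinned.size / train.size - 0.5) < 0.05

    def test_rate_equalization_lowers_rate_not_cv(self):
        rng = np.random.default_rng(11)
        # Poisson unit, rate doubles in state 1; CV should stay ~1 in both
        n_bins = 40_000
        labels = (np.arange(n_bins) // 200) % 2
        rate = np.where(labels == 1, 10.0, 5.0)
        t, spikes = 0.0, []
        while t < n_bins * 0.03:
            b = min(int(t / 0.03), n_bins - 1)
            t += rng.exponential(1 / rate[b])
            spikes.append(t)
        out = vb.state_matched_isi_cv([np.array(spikes)], labels, n_boot=5, seed=1)
        assert np.all(np.abs(out[:, 0] - 1.0) < 0.15)

    def test_null_fano_difference_across_states(self):
        rng = np.random.default_rng(12)
        n_trials, n_windows = 40, 60
        counts = rng.poisson(2.0, size=(n_trials, n_windows)).astype(float)
        ws = np.tile(rng.integers(0, 2, n_windows), (n_trials, 1))
        out = vb.state_matched_fano(counts, ws, min_trials=10, n_boot=10, seed=2)
        assert abs(out[0] - out[1]) < 0.15
        assert np.all(np.abs(out - 1.0) < 0.2)

    def test_dispatcher_validates_metric(self):
        with pytest.raises(ValueError, match="unknown metric"):
            vb.state_matched_metric(None, None, metric="nope")
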