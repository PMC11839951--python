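"""Generator-level ground-truth checks: determinism, stationarity,
spectral structure, renewal statistics and encoding-target consistency."""

import numpy as np
import pytest

from statecode import information, lfp, synthetic, variability


def _ten_dim_hmm(seed=0):
    rng = np.random.default_rng(seed)
    T = np.full((3, 3), 0.01)
    np.fill_diagonal(T, 0.98)
    return synthetic.GroundTruthHmm(
        T,
        rng.normal(0, 1.5, (3, 10)),
        rng.uniform(0.5, 1.5, (3, 10)),
    )


class TestStateSequence:
    def test_deterministic_under_fixed_seed(self, ground_truth):
        l1, o1 = synthetic.simulate_state_sequence(ground_truth, 500, seed=3)
        l2, o2 = synthetic.simulate_state_sequence(ground_truth, 500, seed=3)
        assert np.array_equal(l1, l2)
        assert np.array_equal(o1, o2)

    def test_ten_dim_validation_shape(self):
        _, obs = synthetic.simulate_state_sequence(_ten_dim_hmm(), 60_000, seed=0)
        assert obs.shape == (60_000, 10)

    def test_occupancy_matches_stationary_distribution(self, ground_truth):
        labels, _ = synthetic.simulate_state_sequence(ground_truth, 60_000, seed=5)
        occ = np.bincount(labels, minlength=3) / labels.size
        pi = synthetic.stationary_distribution(ground_truth.transition_matrix)
        assert np.abs(occ - pi).max() < 0.02
        kl = np.sum(pi * np.log(pi / occ))
        assert kl < 0.01

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic.GroundTruthHmm(
                np.array([[0.9, 0.2], [0.5, 0.5]]), np.zeros((2, 2)), np.ones((2, 2))
            )

    def test_labels_within_range(self, ground_truth):
        labels, _ = synthetic.simulate_state_sequence(ground_truth, 1000, seed=1)
        assert labels.min() >= 0 and labels.max() < ground_truth.n_states


class TestLfpAndBehavior:
    def test_coupling_bounds_enforced(self, ground_truth):
        labels, _ = synthetic.simulate_state_sequence(ground_truth, 50, seed=0)
        with pytest.raises(ValueError, match="coupling"):
            synthetic.simulate_lfp_and_behavior(
                labels, ground_truth.band_power_profile, 1.5, seed=0
            )

    @pytest.mark.parametrize("coupling", [0.0, 1.0])
    def test_behavior_state_information_scales_with_coupling(self, ground_truth, coupling):
        labels, _ = synthetic.simulate_state_sequence(ground_truth, 500, seed=3)
        _, behavior = synthetic.simulate_lfp_and_behavior(
            labels, ground_truth.band_power_profile, coupling, seed=4, n_channels=1
        )
        rng = np.random.default_rng(5)
        for trace in behavior.values():
            mi = information.state_behavior_mi(labels, trace).normalized
            null = [
                information.state_behavior_mi(rng.permutation(labels), trace).normalized
                for _ in range(10)
            ]
            if coupling == 0.0:
                assert mi <= np.percentile(null, 95) + 0.02
            else:
                assert mi > np.percentile(null, 95)

    def test_gamma_dominant_state_has_elevated_gamma_envelope(self):
        gt = synthetic.default_ground_truth(gamma_contrast=10.0, n_channels=1)
        labels, _ = synthetic.simulate_state_sequence(gt, 1500, seed=7)
        sig, _ = synthetic.simulate_lfp_and_behavior(
            labels, gt.band_power_profile, 1.0, seed=8, n_channels=1
        )
        env = lfp.band_envelopes(sig, fs=1250.0)
        n = min(env.n_bins, labels.size)
        gamma = env.values[0, 2:, :n].mean(axis=0)
        for s in (1, 2):
            assert gamma[labels[:n] == 0].mean() > 2 * gamma[labels[:n] == s].mean()

    def test_band_envelopes_separate_states_linearly(self, ground_truth):
        # a linear readout of the 4-band envelopes recovers the state
        from sklearn.linear_model import LogisticRegression

        labels, _ = synthetic.simulate_state_sequence(ground_truth, 2000, seed=9)
        sig, _ = synthetic.simulate_lfp_and_behavior(
            labels, ground_truth.band_power_profile, 1.0, seed=10, n_channels=3
        )
        env = lfp.band_envelopes(sig, fs=1250.0)
        n = min(env.n_bins, labels.size)
        X = env.to_observations()[:n]
        clf = LogisticRegression(max_iter=1000).fit(X, labels[:n])
        assert clf.score(X, labels[:n]) > 0.90


class TestSpikes:
    def test_zero_rate_unit_never_fires(self):
        sp = synthetic.simulate_spikes(
            np.zeros(200, int), np.array([[0.0], [5.0]]).T, n_trials=3, seed=0
        )
        assert all(s.size == 0 for s in sp[0])

    def test_poisson_mean_count(self):
        rate, n_bins, n_trials = 5.0, 1000, 50
        sp = synthetic.simulate_spikes(
            np.zeros(n_bins, int), np.array([[rate]]), n_trials=n_trials, seed=3
        )
        counts = np.array([s.size for s in sp[0]])
        expect = rate * n_bins * 0.03
        se = np.sqrt(expect / n_trials)
        assert abs(counts.mean() - expect) < 3 * se

    def test_spike_times_strictly_increasing(self):
        sp = synthetic.simulate_spikes(
            np.zeros(500, int), np.full((3, 1), 20.0), n_trials=2, seed=1
        )
        for unit in sp:
            for train in unit:
                assert np.all(np.diff(train) > 0)

    def test_shared_factor_increases_count_correlations(self):
        n_units, n_bins, n_trials = 10, 100, 40
        rates = np.full((n_units, 1), 10.0)
        means = []
        for g in (0.0, 0.4, 0.8):
            sp = synthetic.simulate_spikes(
                np.zeros(n_bins, int), rates, shared_factor_strength=g,
                n_trials=n_trials, seed=11,
            )
            counts = np.array([[t.size for t in unit] for unit in sp])
            c = np.corrcoef(counts)
            means.append(c[np.triu_indices(n_units, 1)].mean())
        assert abs(means[0]) < 0.1
        assert means[0] < means[1] < means[2]

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_spikes(np.zeros(10, int), np.ones((1, 1)), n_trials=0)
        with pytest.raises(ValueError):
            synthetic.simulate_spikes(np.zeros(10, int), np.ones((1, 1)), renewal_shape=0)

    def test_gamma_renewal_regularizes_isis(self):
        sp = synthetic.simulate_spikes(
            np.zeros(15_000, int), np.array([[5.0]]), renewal_shape=4.0, seed=2
        )
        cv = variability.isi_cv(sp[0][0])
        assert abs(cv - 0.5) < 0.05  # renewal theory: CV = 1/sqrt(shape)


class TestEncodingTargets:
    def test_noiseless_linear_target_reproducible(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        w = np.array([[1.0, -1.0, 0.5, 0.0]])
        y = synthetic.generate_targets(X, np.zeros(200, int), w, noise_sd=0.0)
        assert np.allclose(y, X @ w[0])

    def test_deterministic_regeneration(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3)) * 0.3
        st = rng.integers(0, 2, 300)
        w = rng.normal(size=(2, 3))
        y1 = synthetic.generate_targets(X, st, w, link="log", seed=9)
        y2 = synthetic.generate_targets(X, st, w, link="log", seed=9)
        assert np.array_equal(y1, y2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weight dimension"):
            synthetic.generate_targets(np.ones((10, 3)), np.zeros(10, int), np.ones((1, 4)))

    def test_opposite_sign_weights_recovered_per_state(self):
        # least-squares per ground-truth state partition recovers the signs
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 3))
        st = rng.integers(0, 2, 2000)
        w = np.array([[2.0, 0.5, -1.0], [-2.0, 0.5, -1.0]])
        y = synthetic.generate_targets(X, st, w, noise_sd=0.1, seed=3)
        for s in (0, 1):
            beta = np.linalg.lstsq(X[st == s], y[st == s], rcond=None)[0]
            assert np.sign(beta[0]) == np.sign(w[s, 0])
            assert np.abs(beta - w[s]).max() < 0.1


class TestSessionBundle:
    def test_roundtrip(self, tmp_path):
        sess = synthetic.simulate_session(
            duration_s=30.0, n_units=4, trial_len_s=15.0, seed=5,
            movie_shape=(24, 32), n_channels=1,
        )
        sess.save(tmp_path / "bundle")
        back = synthetic.SyntheticSession.load(tmp_path / "bundle")
        assert np.array_equal(back.true_states, sess.true_states)
        assert np.allclose(back.lfp, sess.lfp)
        assert back.movie.dtype == np.uint8
        assert set(back.behavior) == set(sess.behavior)
        assert all(
            np.allclose(a, b)
            for u in range(4)
            for a, b in zip(back.spikes[u], sess.spikes[u])
        )
        assert len(back.units) == 4
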