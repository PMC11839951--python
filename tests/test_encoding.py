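"""Design matrices, state-balanced folds, state-conditioned fits and
variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from statecode import encoding as enc
from statecode import synthetic


def _blocks(n=3000, seed=0):
    rng = np.random.default_rng(seed)
    return [
        enc.FeatureBlock("stim", "stimulus", rng.normal(size=(n, 3))),
        enc.FeatureBlock("beh", "behavior", rng.normal(size=(n, 4))),
        enc.FeatureBlock("lfp", "internal-lfp", rng.normal(size=(n, 2))),
        enc.FeatureBlock("pop", "internal-population", rng.normal(size=(n, 1))),
    ]


class TestDesignMatrix:
    def test_lag_column_count(self):
        d = enc.build_design_matrix(_blocks(), tau_s=0.5)
        assert d.n_lags == 15
        per_feature = d.columns.groupby("feature").size()
        assert (per_feature == 15).all()
        assert d.X.shape[1] == 10 * 15

    def test_full_scheme_internal_orthogonal_to_rest(self):
        d = enc.build_design_matrix(_blocks(), tau_s=0.2, scheme="full")
        F = d.features_pre_lag
        cat = d.feature_meta["category"].to_numpy()
        internal = np.isin(cat, ("internal-lfp", "internal-population"))
        C = np.corrcoef(F.T)
        assert np.abs(C[np.ix_(internal, ~internal)]).max() < 1e-8

    def test_behavior_orthogonalized_within_group(self):
        d = enc.build_design_matrix(_blocks(), tau_s=0.2)
        beh = d.feature_meta["category"].to_numpy() == "behavior"
        B = d.features_pre_lag[:, beh]
        G = B.T @ B
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_unique_scheme_keeps_cross_group_correlation(self):
        rng = np.random.default_rng(1)
        stim = rng.normal(size=(2000, 2))
        internal = stim @ rng.normal(size=(2, 2)) + 0.1 * rng.normal(size=(2000, 2))
        blocks = [
            enc.FeatureBlock("stim", "stimulus", stim),
            enc.FeatureBlock("lfp", "internal-lfp", internal),
        ]
        d = enc.build_design_matrix(blocks, tau_s=0.1, scheme="unique-category")
        F = d.features_pre_lag
        cat = d.feature_meta["category"].to_numpy()
        C = np.corrcoef(F.T)
        cross = np.abs(C[np.ix_(cat == "internal-lfp", cat == "stimulus")])
        assert cross.max() > 0.5  # unique scheme must NOT decorrelate across groups

    def test_toeplitz_lag_structure(self):
        n = 200
        x = np.arange(n, dtype=float)
        d = enc.build_design_matrix(
            [enc.FeatureBlock("s", "stimulus", x[:, None])], tau_s=0.1
        )
        col0 = d.X[:, d.columns["lag"] == 0].ravel()
        col2 = d.X[:, d.columns["lag"] == 2].ravel()
        assert np.allclose(col0[:-2] - col2[2:], 0.0)

    def test_row_offset_drops_incomplete_rows(self):
        d = enc.build_design_matrix(_blocks(300), tau_s=0.3)
        assert d.row_offset == d.n_lags - 1
        assert d.X.shape[0] == 300 - d.n_lags + 1
        assert np.all(np.isfinite(d.X))

    def test_excessive_tau_rejected(self):
        with pytest.raises(ValueError, match="session length"):
            enc.build_design_matrix(_blocks(50), tau_s=2.0)

    def test_rank_deficient_block_flagged(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=(500, 2))
        blocks = [
            enc.FeatureBlock("beh", "behavior", np.column_stack([b, b[:, 0]])),
        ]
        with pytest.warns(RuntimeWarning, match="near-dependent"):
            d = enc.build_design_matrix(blocks, tau_s=0.1)
        assert d.flagged_columns


class TestStateBalancedFolds:
    def test_single_state_reduces_to_contiguous_kfold(self):
        f = enc.state_balanced_folds(np.zeros(100, int), k=5)
        assert np.array_equal(f, np.repeat(np.arange(5), 20))

    def test_fold_proportions_match_global(self):
        rng = np.random.default_rng(3)
        states = rng.choice([0, 1, 2], size=3000, p=[0.2, 0.3, 0.5])
        f = enc.state_balanced_folds(states, k=5)
        glob = np.bincount(states, minlength=3) / states.size
        for j in range(5):
            prop = np.bincount(states[f == j], minlength=3) / (f == j).sum()
            assert np.abs(prop - glob).max() < 0.02

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        states = rng.integers(0, 3, 500)
        f = enc.state_balanced_folds(states, k=5)
        assert f.min() >= 0 and np.bincount(f).sum() == 500

    def test_rare_state_error_names_state(self):
        states = np.zeros(100, int)
        states[0] = 7
        with pytest.raises(ValueError, match="state 7"):
            enc.state_balanced_folds(states, k=5)


class TestStateConditionedFit:
    def test_large_penalty_shrinks_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=500)
        m = enc.StateConditionedRegression(lambda_grid=[1e8]).fit(X, y, np.zeros(500, int))
        assert np.linalg.norm(m.coef_[0]) < 1e-4

    def test_noiseless_single_state_recovery(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1500, 5))
        beta = np.array([1.0, -2.0, 0.0, 0.5, 3.0])
        y = X @ beta
        m = enc.StateConditionedRegression(lambda_grid=[1e-6]).fit(X, y, np.zeros(1500, int))
        mu, sd = m.scaler_[0]
        rel = np.abs(m.coef_[0] / sd - beta).max() / np.abs(beta).max()
        assert rel < 1e-3

    def test_per_state_weights_recovered_pooled_model_fails(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4000, 4))
        st = rng.integers(0, 2, 4000)
        W = np.array([[2.0, -1.0, 0.5, 0.0], [-2.0, 1.0, -0.5, 0.0]])
        y = synthetic.generate_targets(X, st, W)
        m = enc.StateConditionedRegression(lambda_grid=[1e-6]).fit(X, y, st)
        for s in (0, 1):
            mu, sd = m.scaler_[s]
            rel = np.abs(m.coef_[s] / sd - W[s]).max() / np.abs(W).max()
            assert rel < 1e-2
        pooled = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(pooled - W[0]).max() / np.abs(W).max() > 0.5

    def test_poisson_recovery_within_fisher_se(self):
        rng = np.random.default_rng(8)
        n = 20_000
        X = rng.normal(size=(n, 3)) * 0.3
        theta = np.array([0.5, -0.3, 0.2])
        y = rng.poisson(np.exp(X @ theta)).astype(float)
        m = enc.StateConditionedRegression(link="log", lambda_grid=[1e-9]).fit(
            X, y, np.zeros(n, int)
        )
        mu_s, sd = m.scaler_[0]
        theta_hat = m.coef_[0] / sd
        mu_rate = np.exp(X @ theta)
        fisher = X.T @ (X * mu_rate[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(fisher)))
        assert np.all(np.abs(theta_hat - theta) < 3 * se + 1e-3)

    def test_poisson_mean_positive(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(800, 3))
        y = rng.poisson(1.0, 800).astype(float)
        m = enc.StateConditionedRegression(link="log", lambda_grid=[1.0]).fit(
            X, y, np.zeros(800, int)
        )
        assert (m.predict(X, np.zeros(800, int)) > 0).all()

    def test_negative_poisson_target_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            enc.StateConditionedRegression(link="log").fit(
                np.zeros((10, 2)), np.array([1.0] * 9 + [-1.0]), np.zeros(10, int)
            )

    def test_nonfinite_target_rejected(self):
        y = np.zeros(10)
        y[0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            enc.StateConditionedRegression().fit(np.zeros((10, 2)), y, np.zeros(10, int))


class TestCvR2:
    def test_formula_endpoints_and_half_case(self):
        y = np.array([1.0, 2.0, 3.0])
        assert enc.r2_score_eq(y, y) == 1.0
        assert enc.r2_score_eq(y, np.full(3, y.mean())) == 0.0
        assert enc.r2_score_eq(y, np.array([1.0, 2.0, 2.0])) == pytest.approx(0.5)

    def test_concatenated_r2_consistent_with_per_state(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 3))
        st = np.zeros(2000, int)
        y = X @ np.array([1.0, 2.0, -1.0]) + 0.1 * rng.normal(size=2000)
        folds = enc.state_balanced_folds(st, k=5)
        ev = enc.evaluate_cv_r2(
            X, y, st, folds, enc.StateConditionedRegression(lambda_grid=[1e-6])
        )
        assert ev.r2_full > 0.98
        assert ev.r2_per_state[0] == pytest.approx(ev.r2_full, abs=0.02)

    def test_smoothing_changes_target(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(600, 2))
        y = rng.poisson(1.0, 600).astype(float)
        st = np.zeros(600, int)
        folds = enc.state_balanced_folds(st, k=3)
        m = enc.StateConditionedRegression(lambda_grid=[1.0])
        ev_raw = enc.evaluate_cv_r2(X, y, st, folds, m)
        ev_smooth = enc.evaluate_cv_r2(X, y, st, folds, m, smoothing_sd_s=0.05)
        assert ev_raw.r2_full != ev_smooth.r2_full


class TestPartitioning:
    def test_planted_stimulus_source_recovered(self):
        rng = np.random.default_rng(12)
        blocks = _blocks(2500, seed=12)
        d = enc.build_design_matrix([blocks[0]], tau_s=0.1, scheme="unique-category")
        w = rng.normal(size=(1, d.X.shape[1]))
        y = np.zeros(2500)
        y[d.row_offset :] = d.X @ w[0]
        y += 0.05 * rng.normal(size=2500)
        states = rng.integers(0, 2, 2500)
        rep = enc.partition_contributions(
            blocks, y, states, tau_s=0.1, k_folds=3, lambda_grid=np.array([1e-4]), seed=0
        )
        assert rep.per_category["stimulus"].r2_full > rep.full.r2_full - 0.05
        assert rep.per_category["behavior"].r2_full < 0.05

    def test_delta_definition_exact(self):
        rng = np.random.default_rng(13)
        blocks = _blocks(1500, seed=13)
        y = rng.normal(size=1500)
        states = rng.integers(0, 2, 1500)
        rep = enc.partition_contributions(
            blocks, y, states, tau_s=0.1, k_folds=3, lambda_grid=np.array([1.0]), seed=1
        )
        assert rep.delta_internal == pytest.approx(
            rep.full.r2_full - rep.combined_stim_behavior.r2_full
        )

    def test_planted_variance_share_ordering(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            blocks = [
                enc.FeatureBlock("stim", "stimulus", rng.normal(size=(n, 2))),
                enc.FeatureBlock("beh", "behavior", rng.normal(size=(n, 2))),
                enc.FeatureBlock("lfp", "internal-lfp", rng.normal(size=(n, 2))),
            ]
            parts = [np.sqrt(s) * b.values.sum(axis=1) for s, b in zip((0.5, 0.3, 0.2), blocks)]
            y = sum(parts) + 0.2 * rng.normal(size=n)
            rep = enc.partition_contributions(
                blocks, y, rng.integers(0, 2, n), tau_s=0.1, k_folds=3,
                lambda_grid=np.array([1e-2]), seed=seed,
            )
            r2 = [rep.per_category[c].r2_full for c in ("stimulus", "behavior", "internal-lfp")]
            wins += int(r2[0] > r2[1] > r2[2])
        assert wins >= 3  # majority over seeds

    def test_absent_category_skipped_with_warning(self):
        rng = np.random.default_rng(14)
        blocks = [_blocks(800, seed=14)[0]]
        with pytest.warns(RuntimeWarning, match="absent"):
            rep = enc.partition_contributions(
                blocks, rng.normal(size=800), rng.integers(0, 2, 800),
                tau_s=0.1, k_folds=3, lambda_grid=np.array([1.0]),
            )
        assert rep.delta_internal is None


class TestUnitFilters:
    @staticmethod
    def _units():
        return pd.DataFrame(
            {
                "presence_ratio": [0.92, 0.99, 0.99],
                "isi_violations": [0.1, 0.1, 0.1],
                "amplitude_cutoff": [0.05, 0.05, 0.05],
                "rf_x": [60.0, 60.0, 60.0],
                "rf_y": [45.0, 45.0, 45.0],
            }
        )

    def test_tighter_encoding_presence_threshold(self):
        units = self._units()
        rates = np.full((3, 3), 5.0)
        base = enc.filter_units(units, enc.UnitFilterCriteria(), rates)
        tight = enc.filter_units(units, enc.UnitFilterCriteria.encoding(), rates)
        assert base[0] and not tight[0]

    def test_all_states_rate_rule(self):
        units = self._units()
        rates = np.full((3, 3), 5.0)
        rates[1, 2] = 0.8  # below 1 spk/s in one state
        mask = enc.filter_units(units, enc.UnitFilterCriteria(), rates)
        assert not mask[1] and mask[0] and mask[2]

    def test_disabled_criteria_keep_all(self):
        crit = enc.UnitFilterCriteria(None, None, None, None, None)
        assert enc.filter_units(self._units(), crit).all()

    def test_rf_margin(self):
        units = self._units()
        units.loc[2, "rf_x"] = 10.0  # within 20 deg of the screen edge
        mask = enc.filter_units(
            units, enc.UnitFilterCriteria(min_rate_per_state=None)
        )
        assert not mask[2] and mask[0]

    def test_missing_column_named(self):
        units = self._units().drop(columns=["isi_violations"])
        with pytest.raises(KeyError, match="isi_violations"):
            enc.filter_units(units, enc.UnitFilterCriteria(min_rate_per_state=None))
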