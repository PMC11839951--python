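"""State-conditioned encoding models.

Design matrices are built from category-tagged feature blocks
(stimulus, behavior, internal brain activity), orthogonalized with QR
before lag expansion — behavioral features among themselves, internal
features against everything preceding them — then expanded into
Toeplitz lag blocks at 30 Hz.  One regressor is fit per oscillation
state (ridge for the population target, an L2-penalized Poisson GLM for
single neurons) on state-balanced cross-validation folds, and explained
variance is partitioned across feature categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import PoissonRegressor, Ridge
from sklearn.model_selection import KFold

__all__ = [
    "CATEGORIES",
    "FeatureBlock",
    "LaggedDesignMatrix",
    "UnitFilterCriteria",
    "EncodingEvaluation",
    "ContributionReport",
    "build_design_matrix",
    "state_balanced_folds",
    "StateConditionedRegression",
    "fit_state_model",
    "r2_score_eq",
    "evaluate_cv_r2",
    "partition_contributions",
    "per_state_rates",
    "filter_units",
]

CATEGORIES = ("stimulus", "behavior", "internal-lfp", "internal-population")
_INTERNAL = ("internal-lfp", "internal-population")


@dataclass
class FeatureBlock:
    """A named group of time-aligned features at 30 Hz."""

    name: str
    category: str
    values: np.ndarray  # (n_bins, n_features)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.values.shape[1] > 1:
            self.values = self.values.T
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r} contains non-finite values")


@dataclass
class LaggedDesignMatrix:
    """Orthogonalized, lag-expanded design matrix.

    ``X`` is (n_bins - n_lags + 1, n_features * n_lags); row ``i`` of
    ``X`` corresponds to session bin ``i + row_offset``.
    ``features_pre_lag`` holds the centered, orthogonalized feature
    columns before lag expansion (the matrix on which the
    orthogonalization guarantees hold exactly).
    """

    X: np.ndarray
    columns: pd.DataFrame  # block, category, feature, lag
    features_pre_lag: np.ndarray
    feature_meta: pd.DataFrame  # block, category, feature
    n_lags: int
    row_offset: int
    tau_s: float
    scheme: str
    flagged_columns: list[str] = field(default_factory=list)

    def category_columns(self, categories: str | tuple[str, ...]) -> np.ndarray:
        if isinstance(categories, str):
            categories = (categories,)
        return np.flatnonzero(self.columns["category"].isin(categories).to_numpy())


def _qr_orthogonalize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Economy QR; returns (Q, mask of near-dependent columns)."""
    Q, R = np.linalg.qr(M)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    return Q, bad


def build_design_matrix(
    blocks: list[FeatureBlock],
    tau_s: float,
    scheme: str = "full",
    bin_s: float = 1.0 / 30.0,
) -> LaggedDesignMatrix:
    """Assemble the lagged, orthogonalized design matrix.

    Column order is [stimulus, behavior, internal-lfp,
    internal-population].  All columns are centered.  Under the ``full``
    scheme stimulus features stay raw, behavioral features are
    QR-orthogonalized among themselves, and internal features are
    orthogonalized against every preceding column (QR of the whole
    matrix, keeping the trailing columns).  Under ``unique-category``
    each category is only orthogonalized within itself (used for
    single-category contribution models).  QR runs before lag
    expansion; each feature then becomes ``round(tau_s / bin_s)``
    time-shifted (Toeplitz) columns and the incomplete leading rows are
    dropped.
    """
    if scheme not in ("full", "unique-category"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n_lags = int(round(tau_s / bin_s))
    if n_lags < 1 or abs(n_lags * bin_s - tau_s) > 1e-6:
        raise ValueError("tau_s must be a positive multiple of the bin width")
    blocks = sorted(blocks, key=lambda b: CATEGORIES.index(b.category))
    n_bins = blocks[0].values.shape[0]
    for b in blocks:
        if b.values.shape[0] != n_bins:
            raise ValueError(f"block {b.name!r} is not time-aligned")
    if n_lags >= n_bins:
        raise ValueError("tau exceeds the session length")
    cols, meta = [], []
    for b in blocks:
        for j in range(b.values.shape[1]):
            cols.append(b.values[:, j])
            meta.append({"block": b.name, "category": b.category, "feature": f"{b.name}:{j}"})
    F = np.column_stack(cols)
    F = F - F.mean(axis=0)
    meta = pd.DataFrame(meta)
    cat = meta["category"].to_numpy()
    flagged: list[str] = []
    beh = np.flatnonzero(cat == "behavior")
    if beh.size > 1:
        Q, bad = _qr_orthogonalize(F[:, beh])
        F[:, beh] = Q
        flagged += list(meta.loc[beh[bad], "feature"])
    internal = np.flatnonzero(np.isin(cat, _INTERNAL))
    if internal.size:
        if scheme == "full":
            Q, bad = _qr_orthogonalize(F)
            F[:, internal] = Q[:, internal]
            flagged += list(meta.loc[internal[bad[internal]], "feature"])
        else:
            Q, bad = _qr_orthogonalize(F[:, internal])
            F[:, internal] = Q
            flagged += list(meta.loc[internal[bad], "feature"])
    if flagged:
        warnings.warn(f"near-dependent feature columns: {flagged}", RuntimeWarning)
    # Toeplitz lag expansion: lag l column holds the feature l bins in the past
    n_feat = F.shape[1]
    n_rows = n_bins - n_lags + 1
    X = np.empty((n_rows, n_feat * n_lags))
    col_meta = []
    for j in range(n_feat):
        for lag in range(n_lags):
            X[:, j * n_lags + lag] = F[n_lags - 1 - lag : n_bins - lag, j]
            col_meta.append(
                {
                    "block": meta.loc[j, "block"],
                    "category": meta.loc[j, "category"],
                    "feature": meta.loc[j, "feature"],
                    "lag": lag,
                }
            )
    return LaggedDesignMatrix(
        X=X,
        columns=pd.DataFrame(col_meta),
        features_pre_lag=F,
        feature_meta=meta,
        n_lags=n_lags,
        row_offset=n_lags - 1,
        tau_s=tau_s,
        scheme=scheme,
        flagged_columns=flagged,
    )


def state_balanced_folds(
    states: np.ndarray, k: int = 5, seed: int | None = None
) -> np.ndarray:
    """Fold assignment with equitable per-state representation.

    For every state its bins (in temporal order) are split into ``k``
    contiguous chunks and chunk ``j`` goes to fold ``j``; each fold's
    state composition therefore matches the global one up to rounding,
    and with a single state the scheme reduces to plain contiguous
    k-fold.  Every bin lands in exactly one fold.
    """
    states = np.asarray(states, dtype=int)
    folds = np.full(states.size, -1, dtype=int)
    for s in np.unique(states):
        idx = np.flatnonzero(states == s)
        if idx.size < k:
            raise ValueError(
                f"state {s} has only {idx.size} bins; cannot stratify into {k} folds"
            )
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[chunk] = j
    return folds


class StateConditionedRegression(BaseEstimator, RegressorMixin):
    """One regularized regressor per oscillation state.

    ``link='identity'`` fits ridge regression per state;
    ``link='log'`` fits an L2-penalized Poisson GLM (log link) per
    state.  Feature standardization statistics come from the training
    rows of each state only.  The per-state penalty ``lambda_s`` is
    selected on a random 30% subset with 3-fold cross-validation of R^2
    for the identity link, and by nested k-fold (default 5) for the log
    link.  The intercept is never penalized.

    Attributes (after ``fit``)
    --------------------------
    coef_ : dict state -> weight vector (on standardized features)
    intercept_ : dict state -> intercept
    lambda_ : dict state -> selected penalty
    scaler_ : dict state -> (mean, sd) used for standardization
    """

    def __init__(
        self,
        link: str = "identity",
        lambda_grid: np.ndarray | None = None,
        lambda_folds: int = 3,
        lambda_subset: float = 0.3,
        nested_folds: int = 5,
        random_state: int | None = None,
    ):
        self.link = link
        self.lambda_grid = lambda_grid
        self.lambda_folds = lambda_folds
        self.lambda_subset = lambda_subset
        self.nested_folds = nested_folds
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.asarray(self.lambda_grid, dtype=float)
        return np.logspace(-2, 4, 13)

    def _make(self, lam: float):
        if self.link == "identity":
            return Ridge(alpha=lam)
        return PoissonRegressor(alpha=lam, max_iter=1000, tol=1e-6)

    def fit(self, X: np.ndarray, y: np.ndarray, states: np.ndarray) -> "StateConditionedRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        states = np.asarray(states, dtype=int)
        if self.link not in ("identity", "log"):
            raise ValueError(f"unknown link {self.link!r}")
        if not np.all(np.isfinite(y)):
            raise ValueError("target contains non-finite values")
        if self.link == "log" and np.any(y < 0):
            raise ValueError("Poisson targets must be non-negative")
        if X.shape[0] != y.size or X.shape[0] != states.size:
            raise ValueError("X, y and states must share their first dimension")
        rng = np.random.default_rng(self.random_state)
        grid = self._grid()
        self.states_ = np.unique(states)
        self.coef_, self.intercept_, self.lambda_, self.scaler_ = {}, {}, {}, {}
        for s in self.states_:
            idx = np.flatnonzero(states == s)
            if idx.size < X.shape[1] / 10:
                warnings.warn(
                    f"state {s}: only {idx.size} training rows for {X.shape[1]} columns",
                    RuntimeWarning,
                )
            mu = X[idx].mean(axis=0)
            sd = X[idx].std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (X[idx] - mu) / sd
            ys = y[idx]
            lam = self._select_lambda(Xs, ys, grid, rng)
            model = self._make(lam).fit(Xs, ys)
            self.coef_[s] = model.coef_.copy()
            self.intercept_[s] = float(model.intercept_)
            self.lambda_[s] = float(lam)
            self.scaler_[s] = (mu, sd)
        return self

    def _select_lambda(self, Xs, ys, grid, rng) -> float:
        if grid.size == 1:
            return float(grid[0])
        if self.link == "identity":
            n = Xs.shape[0]
            m = max(min(n, 30), int(round(self.lambda_subset * n)))
            sub = rng.choice(n, size=m, replace=False)
            Xsub, ysub = Xs[sub], ys[sub]
            cv = KFold(n_splits=min(self.lambda_folds, max(2, m // 10)))
        else:
            Xsub, ysub = Xs, ys
            cv = KFold(n_splits=self.nested_folds)
        best_lam, best = float(grid[0]), -np.inf
        for lam in grid:
            scores = []
            for tr, te in cv.split(Xsub):
                if ysub[te].std() == 0:
                    continue
                mdl = self._make(lam).fit(Xsub[tr], ysub[tr])
                scores.append(r2_score_eq(ysub[te], mdl.predict(Xsub[te])))
            score = np.mean(scores) if scores else -np.inf
            if score > best:
                best, best_lam = score, float(lam)
        return best_lam

    def predict(self, X: np.ndarray, states: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        states = np.asarray(states, dtype=int)
        out = np.empty(X.shape[0])
        for s in np.unique(states):
            idx = np.flatnonzero(states == s)
            if s not in self.coef_:
                # unseen state: fall back to the nearest trained state's model
                s_use = self.states_[np.argmin(np.abs(self.states_ - s))]
            else:
                s_use = s
            mu, sd = self.scaler_[s_use]
            Xs = (X[idx] - mu) / sd
            eta = Xs @ self.coef_[s_use] + self.intercept_[s_use]
            out[idx] = np.exp(eta) if self.link == "log" else eta
        return out


def fit_state_model(
    X: np.ndarray,
    y: np.ndarray,
    states: np.ndarray,
    link: str = "identity",
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> StateConditionedRegression:
    """Fit per-state regressors; thin wrapper over :class:`StateConditionedRegression`."""
    return StateConditionedRegression(
        link=link, lambda_grid=lambda_grid, random_state=seed
    ).fit(X, y, states)


def r2_score_eq(y: np.ndarray, yhat: np.ndarray) -> float:
    """Explained variance ``R^2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)``."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


@dataclass
class EncodingEvaluation:
    """Cross-validated explained variance of a state-conditioned model."""

    r2_full: float  # mean over folds of the concatenated-state R^2
    r2_per_fold: list[float]
    r2_per_state: dict[int, float]
    predictions: np.ndarray | None = None
    n_folds: int = 5


def evaluate_cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    states: np.ndarray,
    folds: np.ndarray,
    model: StateConditionedRegression | None = None,
    smoothing_sd_s: float | None = None,
    bin_s: float = 1.0 / 30.0,
    keep_predictions: bool = False,
) -> EncodingEvaluation:
    """Five-fold (by default) cross-validated explained variance.

    Within each fold the per-state regressors are fit on the training
    rows and their predictions are concatenated across states on the
    test rows; the fold's R^2 follows the explained-variance formula.
    Per-state R^2 pools every row's out-of-fold prediction and restricts
    the formula to that state's rows.  ``smoothing_sd_s`` optionally
    smooths the target with a Gaussian kernel (e.g. 0.05 s for
    single-neuron spike counts) before evaluation.  Folds whose test
    target has zero variance are excluded with a warning.
    """
    y = np.asarray(y, dtype=float)
    states = np.asarray(states, dtype=int)
    folds = np.asarray(folds, dtype=int)
    if smoothing_sd_s:
        y = gaussian_filter1d(y, smoothing_sd_s / bin_s)
    model = model if model is not None else StateConditionedRegression()
    yhat = np.full(y.size, np.nan)
    fold_r2 = []
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        est = clone(model)
        est.fit(X[tr], y[tr], states[tr])
        yhat[te] = est.predict(X[te], states[te])
        if y[te].std() == 0:
            warnings.warn(f"fold {f}: zero-variance target, R^2 undefined", RuntimeWarning)
            continue
        fold_r2.append(r2_score_eq(y[te], yhat[te]))
    per_state = {}
    for s in np.unique(states):
        idx = states == s
        per_state[int(s)] = r2_score_eq(y[idx], yhat[idx])
    return EncodingEvaluation(
        r2_full=float(np.mean(fold_r2)) if fold_r2 else float("nan"),
        r2_per_fold=fold_r2,
        r2_per_state=per_state,
        predictions=yhat if keep_predictions else None,
        n_folds=int(np.unique(folds).size),
    )


@dataclass
class ContributionReport:
    """Variance partition across feature categories for one target."""

    full: EncodingEvaluation
    per_category: dict[str, EncodingEvaluation]
    combined_stim_behavior: EncodingEvaluation | None
    delta_internal: float | None  # cvR^2(full) - cvR^2(stimulus + behavior)
    tau_s: float


def partition_contributions(
    blocks: list[FeatureBlock],
    y: np.ndarray,
    states: np.ndarray,
    tau_s: float,
    k_folds: int = 5,
    link: str = "identity",
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
    smoothing_sd_s: float | None = None,
) -> ContributionReport:
    """Full-model cvR^2 plus single-category and incremental contributions.

    Single-category models use the ``unique-category`` design scheme
    (features orthogonalized only within their own group); the
    incremental contribution of internal brain activity is the
    difference between the full model and the stimulus + behavior model
    on identical folds.  Categories absent from ``blocks`` are skipped
    with a warning.
    """
    present = {b.category for b in blocks}
    full_design = build_design_matrix(blocks, tau_s, scheme="full")
    off = full_design.row_offset
    y_al = np.asarray(y, dtype=float)[off:]
    st_al = np.asarray(states, dtype=int)[off:]
    folds = state_balanced_folds(st_al, k=k_folds, seed=seed)
    mk = lambda: StateConditionedRegression(link=link, lambda_grid=lambda_grid, random_state=seed)
    full_ev = evaluate_cv_r2(
        full_design.X, y_al, st_al, folds, mk(), smoothing_sd_s=smoothing_sd_s
    )
    per_cat: dict[str, EncodingEvaluation] = {}
    for cat in CATEGORIES:
        sub = [b for b in blocks if b.category == cat]
        if not sub:
            warnings.warn(f"category {cat!r} absent; skipped", RuntimeWarning)
            continue
        d = build_design_matrix(sub, tau_s, scheme="unique-category")
        per_cat[cat] = evaluate_cv_r2(
            d.X, y_al, st_al, folds, mk(), smoothing_sd_s=smoothing_sd_s
        )
    sb = [b for b in blocks if b.category in ("stimulus", "behavior")]
    combined = None
    delta = None
    if sb and present & set(_INTERNAL):
        d = build_design_matrix(sb, tau_s, scheme="full")
        combined = evaluate_cv_r2(
            d.X, y_al, st_al, folds, mk(), smoothing_sd_s=smoothing_sd_s
        )
        delta = full_ev.r2_full - combined.r2_full
    return ContributionReport(full_ev, per_cat, combined, delta, tau_s)


def per_state_rates(
    spikes: list[list[np.ndarray]],
    labels: np.ndarray,
    bin_s: float = 0.03,
    trial_len_bins: int | None = None,
) -> np.ndarray:
    """Firing rate (spk/s) of every unit in every state.

    ``spikes[u][trial]`` are spike times within the trial; the session
    state path ``labels`` is split into trials of ``trial_len_bins``.
    """
    labels = np.asarray(labels, dtype=int)
    n_states = labels.max() + 1
    occ = np.array([(labels == s).sum() * bin_s for s in range(n_states)])
    n_units = len(spikes)
    out = np.zeros((n_units, n_states))
    for u in range(n_units):
        for tr, st in enumerate(spikes[u]):
            offset = 0 if trial_len_bins is None else tr * trial_len_bins
            bins = np.floor(np.asarray(st) / bin_s).astype(int) + offset
            bins = bins[(bins >= 0) & (bins < labels.size)]
            np.add.at(out[u], labels[bins], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = out / occ
    out[:, occ == 0] = np.nan
    return out


@dataclass(frozen=True)
class UnitFilterCriteria:
    """Quality-control thresholds; ``None`` disables a criterion.

    Inequalities are strict as printed: presence ratio > min, ISI
    violations < max, amplitude cutoff < max, firing rate > min in every
    state; receptive-field centers must sit at least ``rf_margin_deg``
    inside the screen extent.
    """

    presence_ratio_min: float | None = 0.9
    isi_violations_max: float | None = 0.5
    amplitude_cutoff_max: float | None = 0.1
    min_rate_per_state: float | None = 1.0
    rf_margin_deg: float | None = 20.0

    @classmethod
    def encoding(cls) -> "UnitFilterCriteria":
        """Tighter preset used for single-neuron encoding (presence > 0.95)."""
        return cls(presence_ratio_min=0.95)


def filter_units(
    units: pd.DataFrame,
    criteria: UnitFilterCriteria = UnitFilterCriteria(),
    state_rates: np.ndarray | None = None,
    screen_extent: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 120.0), (0.0, 95.0)),
) -> np.ndarray:
    """Boolean retention mask over the unit table.

    ``state_rates`` (n_units, n_states) backs the all-states minimum-rate
    rule; it is required when that criterion is enabled.  Missing
    metadata columns raise ``KeyError`` naming the column.
    """
    mask = np.ones(len(units), dtype=bool)

    def col(name: str) -> np.ndarray:
        if name not in units.columns:
            raise KeyError(f"units table is missing required column {name!r}")
        return units[name].to_numpy()

    c = criteria
    if c.presence_ratio_min is not None:
        mask &= col("presence_ratio") > c.presence_ratio_min
    if c.isi_violations_max is not None:
        mask &= col("isi_violations") < c.isi_violations_max
    if c.amplitude_cutoff_max is not None:
        mask &= col("amplitude_cutoff") < c.amplitude_cutoff_max
    if c.min_rate_per_state is not None:
        if state_rates is None:
            raise ValueError("state_rates required for the minimum-rate criterion")
        mask &= np.all(np.asarray(state_rates) > c.min_rate_per_state, axis=1)
    if c.rf_margin_deg is not None:
        (x0, x1), (y0, y1) = screen_extent
        rx, ry = col("rf_x"), col("rf_y")
        m = c.rf_margin_deg
        mask &= (rx >= x0 + m) & (rx <= x1 - m) & (ry >= y0 + m) & (ry <= y1 - m)
    return mask
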