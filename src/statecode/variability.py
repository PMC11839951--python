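"""State-resolved neuronal variability metrics.

Three complementary views of variability, each computed per unit and per
oscillation state with the matching procedures that make states
comparable: factor-analysis shared variance (population co-fluctuation),
the ISI coefficient of variation (spike-timing irregularity, ISIs capped
at 2.5 s and firing rates equalized across states), and the Fano factor
(trial-to-trial count variability in 150 ms windows with a >= 10-trial
rule and optional gaze-cluster conditioning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import FactorAnalysis
from sklearn.model_selection import KFold

__all__ = [
    "FaDecomposition",
    "fit_factor_analysis",
    "percent_shared_variance",
    "shared_variance_per_unit",
    "isi_cv",
    "fano_factor",
    "window_state_labels",
    "bin_counts",
    "gaze_clusters",
    "state_matched_metric",
    "state_matched_shared_variance",
    "state_matched_isi_cv",
    "state_matched_fano",
    "thin_spikes",
]


# ---------------------------------------------------------------------------
# factor analysis / shared variance


@dataclass
class FaDecomposition:
    """Factor-analysis fit of a units x bins spike-count matrix.

    The model covariance is ``L @ L.T + diag(psi)``: a shared component
    (loadings ``L``, n_units x m) plus independent per-unit variances.
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_units, m)
    psi: np.ndarray  # (n_units,)
    m: int
    cv_ll: dict[int, float] = field(default_factory=dict)
    kept_units: np.ndarray | None = None  # indices into the original rows


def fit_factor_analysis(
    counts: np.ndarray,
    m_grid: tuple[int, ...] | None = None,
    cv_folds: int = 3,
    seed: int | None = None,
) -> FaDecomposition:
    """Fit FA to spike counts, selecting the factor count by cross-validation.

    ``counts`` is units x bins.  Constant (zero-variance) units are
    dropped with a warning — they carry no covariance information and
    break the fit.  The number of factors maximizes the k-fold
    cross-validated average log-likelihood; the final model is refit on
    all bins at that m.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    sd = counts.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < counts.shape[0]:
        warnings.warn(
            f"dropping {counts.shape[0] - kept.size} constant unit(s) from FA",
            RuntimeWarning,
        )
    X = counts[kept].T  # samples x features
    n_units = kept.size
    if m_grid is None:
        m_grid = tuple(range(1, min(40, n_units - 1) + 1))
    m_grid = tuple(m for m in m_grid if m <= n_units)
    if X.shape[0] <= max(m_grid):
        raise ValueError("need more bins than the largest candidate factor count")
    cv = KFold(n_splits=cv_folds)
    cv_ll: dict[int, float] = {}
    for m in m_grid:
        lls = []
        for tr, te in cv.split(X):
            fa = FactorAnalysis(n_components=m, random_state=seed)
            fa.fit(X[tr])
            lls.append(fa.score(X[te]))
        cv_ll[m] = float(np.mean(lls))
    m_star = max(m_grid, key=lambda m: cv_ll[m])
    fa = FactorAnalysis(n_components=m_star, random_state=seed).fit(X)
    return FaDecomposition(
        mean=fa.mean_,
        loadings=fa.components_.T,
        psi=fa.noise_variance_,
        m=m_star,
        cv_ll=cv_ll,
        kept_units=kept,
    )


def percent_shared_variance(fa: FaDecomposition, k: int) -> float:
    """Percent shared variance of unit ``k``: ``100 * L_k L_k' / (L_k L_k' + psi_k)``."""
    lk2 = float(fa.loadings[k] @ fa.loadings[k])
    denom = lk2 + float(fa.psi[k])
    if denom == 0:
        return float("nan")
    return 100.0 * lk2 / denom


def shared_variance_per_unit(fa: FaDecomposition) -> np.ndarray:
    lk2 = np.einsum("km,km->k", fa.loadings, fa.loadings)
    denom = lk2 + fa.psi
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * lk2 / denom
    out[denom == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# ISI coefficient of variation


def isi_cv(
    spike_times: np.ndarray,
    state_mask: np.ndarray | None = None,
    bin_s: float = 0.03,
    cap: float = 2.5,
) -> float:
    """Coefficient of variation of inter-spike intervals.

    ISIs are collected from spikes falling in bins flagged by
    ``state_mask`` (all spikes when ``None``); intervals longer than
    ``cap`` seconds are discarded so that state dwell-time differences
    cannot bias the ISI range.  Returns ``sigma / mean`` of the
    surviving ISIs, or ``nan`` when fewer than two remain.
    """
    st = np.asarray(spike_times, dtype=float)
    if state_mask is not None:
        mask = np.asarray(state_mask, dtype=bool)
        bins = np.floor(st / bin_s).astype(int)
        valid = (bins >= 0) & (bins < mask.size)
        st = st[valid][mask[bins[valid]]]
    if st.size < 3:
        return float("nan")
    isis = np.diff(st)
    isis = isis[isis <= cap]
    if isis.size < 2:
        return float("nan")
    mu = isis.mean()
    if mu == 0:
        return float("nan")
    return float(isis.std(ddof=1) / mu)


# ---------------------------------------------------------------------------
# Fano factor


def bin_counts(
    spike_times: np.ndarray, duration_s: float, window_s: float = 0.15
) -> np.ndarray:
    """Spike counts in non-overlapping windows tiling [0, duration) from t = 0."""
    n_win = int(np.floor(duration_s / window_s))
    edges = np.arange(n_win + 1) * window_s
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    return counts


def window_state_labels(
    bin_labels: np.ndarray, window_s: float = 0.15, bin_s: float = 0.03
) -> np.ndarray:
    """State of each window; -1 where the window is not in a single state.

    A window carries state ``s`` only if every constituent bin carries
    the hard label ``s`` (strict reading of "for the complete duration").
    """
    bpw = window_s / bin_s
    if abs(bpw - round(bpw)) > 1e-9:
        raise ValueError("window must be an integer number of bins")
    bpw = int(round(bpw))
    n_win = bin_labels.size // bpw
    lab = np.asarray(bin_labels[: n_win * bpw], dtype=int).reshape(n_win, bpw)
    out = np.where((lab == lab[:, :1]).all(axis=1), lab[:, 0], -1)
    return out


def fano_factor(
    trial_counts: np.ndarray,
    window_states: np.ndarray | None = None,
    state: int | None = None,
    min_trials: int = 10,
    gaze_cluster_ids: np.ndarray | None = None,
) -> tuple[float, int]:
    """Time-averaged Fano factor across trials.

    ``trial_counts`` is (n_trials, n_windows) spike counts of one unit in
    non-overlapping 150 ms windows.  ``window_states`` is (n_trials,
    n_windows) state labels (-1 = mixed); with ``state`` given, a window
    contributes only if at least ``min_trials`` trials spent the full
    window in that state, and the FF for that window is var/mean across
    those trials.  With ``gaze_cluster_ids`` (one id per trial) the trial
    rule is applied within each gaze cluster separately.  Windows with
    zero mean count are skipped.

    Returns ``(mean FF over qualifying windows, n_windows_used)``;
    ``(nan, 0)`` when nothing qualifies.
    """
    counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    n_trials, n_windows = counts.shape
    if gaze_cluster_ids is None:
        groups = [np.arange(n_trials)]
    else:
        ids = np.asarray(gaze_cluster_ids)
        groups = [np.flatnonzero(ids == g) for g in np.unique(ids)]
    ffs = []
    for trials in groups:
        for w in range(n_windows):
            use = trials
            if window_states is not None and state is not None:
                use = trials[window_states[trials, w] == state]
            if use.size < min_trials:
                continue
            c = counts[use, w]
            mu = c.mean()
            if mu == 0:
                continue
            ffs.append(c.var(ddof=1) / mu)
    if not ffs:
        return float("nan"), 0
    return float(np.mean(ffs)), len(ffs)


def gaze_clusters(gaze_xy: np.ndarray, n_clusters: int = 5) -> np.ndarray:
    """Ward-linkage hierarchical clustering of 2-D gaze coordinates."""
    gaze_xy = np.asarray(gaze_xy, dtype=float)
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(gaze_xy)


# ---------------------------------------------------------------------------
# state matching / bootstrap equalization


def thin_spikes(
    spike_times: np.ndarray, keep_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. Bernoulli spike deletion (rate equalization by thinning)."""
    st = np.asarray(spike_times, dtype=float)
    if keep_prob >= 1.0:
        return st
    return st[rng.random(st.size) < keep_prob]


def state_matched_shared_variance(
    counts: np.ndarray,
    labels: np.ndarray,
    m_grid: tuple[int, ...] | None = None,
    n_boot: int = 20,
    cv_folds: int = 3,
    seed: int | None = None,
) -> np.ndarray:
    """Per-state per-unit percent shared variance with occupancy matching.

    The lowest-occupancy state sets the sample size; in each of the
    ``n_boot`` repeats the other states are subsampled (without
    replacement) to that size, FA is refit per state (factor count by
    cross-validation within the repeat), and the per-unit shared
    variance is averaged over repeats.  Returns (n_states, n_units).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    labels = np.asarray(labels, dtype=int)
    states = np.unique(labels)
    occ = {s: np.flatnonzero(labels == s) for s in states}
    n_min = min(idx.size for idx in occ.values())
    rng = np.random.default_rng(seed)
    n_units = counts.shape[0]
    out = np.full((states.size, n_units), np.nan)
    for si, s in enumerate(states):
        vals = np.zeros((n_boot, n_units))
        valid = np.zeros((n_boot, n_units), dtype=bool)
        for b in range(n_boot):
            idx = occ[s]
            if idx.size > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            try:
                fa = fit_factor_analysis(
                    counts[:, idx], m_grid=m_grid, cv_folds=cv_folds,
                    seed=None if seed is None else seed + b,
                )
            except ValueError:
                continue
            sv = shared_variance_per_unit(fa)
            vals[b, fa.kept_units] = sv
            valid[b, fa.kept_units] = np.isfinite(sv)
        with np.errstate(invalid="ignore"):
            out[si] = np.where(
                valid.any(axis=0), vals.sum(axis=0) / np.maximum(valid.sum(axis=0), 1), np.nan
            )
    return out


def state_matched_isi_cv(
    spike_times_per_unit: list[np.ndarray],
    labels: np.ndarray,
    bin_s: float = 0.03,
    cap: float = 2.5,
    n_boot: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Per-state per-unit ISI-CV with firing rates equalized across states.

    For each unit the per-state firing rate is computed from
    state-masked spike counts and occupancy; in every bootstrap repeat
    spikes in richer states are Bernoulli-thinned to the unit's lowest
    across-state rate before the CV is evaluated.  Returns
    (n_states, n_units), ``nan`` where fewer than two capped ISIs remain.
    """
    labels = np.asarray(labels, dtype=int)
    states = np.unique(labels)
    rng = np.random.default_rng(seed)
    n_units = len(spike_times_per_unit)
    out = np.full((states.size, n_units), np.nan)
    occ_s = {s: (labels == s).sum() * bin_s for s in states}
    for u, st in enumerate(spike_times_per_unit):
        st = np.asarray(st, dtype=float)
        bins = np.floor(st / bin_s).astype(int)
        valid = (bins >= 0) & (bins < labels.size)
        st, bins = st[valid], bins[valid]
        rates = {}
        for s in states:
            rates[s] = (labels[bins] == s).sum() / occ_s[s] if occ_s[s] > 0 else 0.0
        positive = [r for r in rates.values() if r > 0]
        if not positive:
            continue
        r_min = min(positive)
        for si, s in enumerate(states):
            if rates[s] <= 0:
                continue
            keep_p = r_min / rates[s]
            mask = labels[bins] == s
            cvs = []
            for _ in range(n_boot):
                sel = st[mask]
                sel = thin_spikes(sel, keep_p, rng)
                cvs.append(isi_cv(sel, None, bin_s, cap))
            cvs = np.asarray(cvs)
            if np.isfinite(cvs).any():
                out[si, u] = np.nanmean(cvs)
    return out


def state_matched_fano(
    trial_counts: np.ndarray,
    window_states: np.ndarray,
    min_trials: int = 10,
    n_boot: int = 20,
    seed: int | None = None,
    gaze_cluster_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Per-state Fano factor with sample-size and rate equalization.

    For one unit: per repeat, each state's qualifying windows are
    subsampled to the scarcest state's count (sample-size matching),
    counts are binomially thinned to the lowest per-state mean rate
    (rate matching via dropped spikes), and the FF is averaged over the
    surviving windows; repeats are then averaged.  Returns an array of
    per-state FF values ordered by state id, ``nan`` where no window
    qualifies.
    """
    counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    ws = np.asarray(window_states, dtype=int)
    states = np.unique(ws[ws >= 0])
    rng = np.random.default_rng(seed)

    def qualifying_windows(s: int) -> list[np.ndarray]:
        """Per window: trial indices fully in state s (>= min_trials), per gaze group."""
        n_trials, n_windows = counts.shape
        if gaze_cluster_ids is None:
            groups = [np.arange(n_trials)]
        else:
            ids = np.asarray(gaze_cluster_ids)
            groups = [np.flatnonzero(ids == g) for g in np.unique(ids)]
        wins = []
        for trials in groups:
            for w in range(n_windows):
                use = trials[ws[trials, w] == s]
                if use.size >= min_trials:
                    wins.append((w, use))
        return wins

    wins_by_state = {s: qualifying_windows(s) for s in states}
    n_win_min = min((len(v) for v in wins_by_state.values() if v), default=0)
    mean_rate = {}
    for s in states:
        wins = wins_by_state[s]
        if wins:
            mean_rate[s] = float(
                np.mean([counts[use, w].mean() for w, use in wins])
            )
    r_min = min((r for r in mean_rate.values() if r > 0), default=0.0)
    out = np.full(int(states.max()) + 1 if states.size else 0, np.nan)
    for s in states:
        wins = wins_by_state[s]
        if not wins or n_win_min == 0 or mean_rate.get(s, 0) <= 0 or r_min <= 0:
            continue
        keep_p = min(1.0, r_min / mean_rate[s])
        reps = []
        for _ in range(n_boot):
            chosen = rng.choice(len(wins), size=n_win_min, replace=False)
            ffs = []
            for ci in chosen:
                w, use = wins[ci]
                c = counts[use, w]
                if keep_p < 1.0:
                    c = rng.binomial(c.astype(int), keep_p).astype(float)
                mu = c.mean()
                if mu > 0:
                    ffs.append(c.var(ddof=1) / mu)
            if ffs:
                reps.append(np.mean(ffs))
        if reps:
            out[s] = float(np.mean(reps))
    return out


def state_matched_metric(
    data,
    labels: np.ndarray,
    metric: str,
    n_boot: int = 20,
    seed: int | None = None,
    **kwargs,
) -> np.ndarray:
    """Dispatch to the state-matched version of a variability metric.

    ``metric`` is one of ``'shared_variance'`` (data: units x bins
    counts), ``'cv'`` (data: list of per-unit spike-time arrays) or
    ``'fano'`` (data: trials x windows counts for one unit; pass
    ``window_states`` in kwargs).
    """
    if metric == "shared_variance":
        return state_matched_shared_variance(
            data, labels, n_boot=n_boot, seed=seed, **kwargs
        )
    if metric == "cv":
        return state_matched_isi_cv(data, labels, n_boot=n_boot, seed=seed, **kwargs)
    if metric == "fano":
        return state_matched_fano(data, labels, n_boot=n_boot, seed=seed, **kwargs)
    raise ValueError(f"unknown metric {metric!r}")
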