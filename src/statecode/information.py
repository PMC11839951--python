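"""Matrix-based Renyi entropy and normalized mutual information.

The estimator sidesteps density estimation: samples are mapped into an
RKHS by a Schoenberg (Gaussian-type) kernel, the unit-trace Gram matrix
A is formed, and the alpha-order entropy is computed from its
eigenspectrum, ``S_alpha(A) = log2(sum_j lambda_j^alpha) / (1 - alpha)``
(bits).  Joint entropy is the entropy of the normalized Hadamard product
of the two Gram matrices.  Mutual information is normalized by the
geometric mean of the marginal entropies, constraining it to [0, 1] up
to numerical slack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KernelSpec",
    "MiResult",
    "scott_sigma",
    "gram",
    "renyi_entropy",
    "mutual_information",
    "state_behavior_mi",
    "trialwise_stimulus_mi",
]


@dataclass(frozen=True)
class KernelSpec:
    """Schoenberg kernel with an explicit width ``sigma`` (exponent scale)."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("kernel width sigma must be > 0")


def scott_sigma(X: np.ndarray) -> float:
    """Scott's-rule kernel width for the Schoenberg exponent.

    The per-dimension bandwidth is ``mean SD * N ** (-1 / (d + 4))`` and
    the exponent scale is ``sigma = 2 * d * bandwidth ** 2``: the kernel
    exponent sums squared differences over all ``d`` dimensions, so the
    scale must grow with the dimension or the kernel collapses to the
    identity for high-dimensional samples (e.g. flattened movie frames)
    and the estimator saturates.  For 1-D inputs this is the classical
    ``2 * bandwidth ** 2``.  Degenerate (zero-variance) samples fall
    back to ``sigma = 1`` — the Gram matrix of identical points is
    width-independent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    width = float(X.std(axis=0).mean()) * n ** (-1.0 / (d + 4))
    if width <= 0:
        return 1.0
    return 2.0 * d * width**2


def gram(X: np.ndarray, kernel: KernelSpec | float | None = None) -> np.ndarray:
    """Normalized Gram matrix A of the Schoenberg kernel.

    ``K_ij = exp(-||x_i - x_j||^2 / sigma)``;
    ``A_ij = K_ij / (N sqrt(K_ii K_jj))`` so that trace(A) = 1 and
    ``A_ii = 1/N``.  ``kernel=None`` applies Scott's rule.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite values")
    if kernel is None:
        sigma = scott_sigma(X)
    elif isinstance(kernel, KernelSpec):
        sigma = kernel.sigma
    else:
        sigma = float(kernel)
        if sigma <= 0:
            raise ValueError("kernel width sigma must be > 0")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / sigma)
    n = X.shape[0]
    return K / n  # K_ii = 1 for the Schoenberg kernel


def renyi_entropy(A: np.ndarray, alpha: float = 1.01) -> float:
    """Matrix-based Renyi alpha-order entropy (bits) of a unit-trace Gram matrix.

    Eigenvalues are clipped at zero (floating-point PSD leakage) and
    renormalized to sum to one before powering.
    """
    if alpha <= 0 or alpha == 1.0:
        raise ValueError("alpha must be positive and != 1")
    A = np.asarray(A, dtype=float)
    lam = np.linalg.eigvalsh(A)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues vanish after clipping")
    lam = lam / total
    return float(np.log2(np.sum(lam**alpha)) / (1.0 - alpha))


@dataclass
class MiResult:
    """Raw and normalized mutual information with the marginal entropies."""

    raw: float  # bits
    normalized: float
    h_x: float
    h_y: float
    h_xy: float


def mutual_information(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float = 1.01,
    kernel_x: KernelSpec | float | None = None,
    kernel_y: KernelSpec | float | None = None,
) -> MiResult:
    """Matrix-based mutual information between two sample sets.

    ``MI = S(A) + S(B) - S(A o B / trace(A o B))`` with the normalized
    value ``MI / sqrt(S(A) S(B))``.  Kernel widths default to Scott's
    rule applied to each variable.  A vanishing marginal entropy leaves
    the normalized value undefined (``nan`` with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    A = gram(X, kernel_x)
    B = gram(Y, kernel_y)
    h_x = renyi_entropy(A, alpha)
    h_y = renyi_entropy(B, alpha)
    J = A * B
    J = J / np.trace(J)
    h_xy = renyi_entropy(J, alpha)
    raw = h_x + h_y - h_xy
    denom = h_x * h_y
    if denom <= 0:
        warnings.warn("zero marginal entropy: normalized MI undefined", RuntimeWarning)
        norm = float("nan")
    else:
        norm = raw / np.sqrt(denom)
    return MiResult(raw, norm, h_x, h_y, h_xy)


def state_behavior_mi(
    labels: np.ndarray, trace: np.ndarray, alpha: float = 1.01
) -> MiResult:
    """MI between a discrete state sequence and a continuous behavior trace.

    State labels are one-hot encoded before kernel evaluation so the
    same matrix-based estimator applies.
    """
    labels = np.asarray(labels, dtype=int)
    onehot = np.eye(labels.max() + 1)[labels]
    return mutual_information(onehot, np.asarray(trace, dtype=float).reshape(-1, 1), alpha)


def trialwise_stimulus_mi(
    spike_counts: np.ndarray,
    frames: np.ndarray,
    labels: np.ndarray,
    trial_len_bins: int,
    min_in_state_s: float = 3.0,
    bin_s: float = 0.03,
    downsample: int = 5,
    alpha: float = 1.01,
) -> pd.DataFrame:
    """Per-trial, state-conditioned MI between population activity and frames.

    ``spike_counts`` is units x bins over the whole session,
    ``frames`` the movie clip (n_frames = trial_len_bins, H, W), repeated
    every trial, and ``labels`` the per-bin hard state labels.  Within
    each trial and state, rows are the bins carrying that state's label;
    X is the population count vector and Y the flattened
    ``downsample``-strided frame.  A (trial, state) pair is evaluated
    only when the state occupies at least ``min_in_state_s`` seconds of
    the trial.  Returns a DataFrame (trial, state, raw_mi, norm_mi, n_bins).
    """
    counts = np.atleast_2d(np.asarray(spike_counts, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n_bins = labels.size
    n_trials = n_bins // trial_len_bins
    ds = np.asarray(frames, dtype=float)[:, ::downsample, ::downsample]
    flat = ds.reshape(ds.shape[0], -1)
    min_bins = int(np.ceil(min_in_state_s / bin_s))
    rows = []
    for tr in range(n_trials):
        sl = slice(tr * trial_len_bins, (tr + 1) * trial_len_bins)
        lab_tr = labels[sl]
        cnt_tr = counts[:, sl]
        for s in np.unique(lab_tr):
            idx = np.flatnonzero(lab_tr == s)
            if idx.size < min_bins:
                continue
            X = cnt_tr[:, idx].T
            Y = flat[idx % flat.shape[0]]
            res = mutual_information(X, Y, alpha)
            rows.append(
                {
                    "trial": tr,
                    "state": int(s),
                    "raw_mi": res.raw,
                    "norm_mi": res.normalized,
                    "n_bins": int(idx.size),
                }
            )
    if not rows:
        warnings.warn("no (trial, state) pair satisfied the minimum-dwell rule", RuntimeWarning)
        return pd.DataFrame(columns=["trial", "state", "raw_mi", "norm_mi", "n_bins"])
    return pd.DataFrame(rows)
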