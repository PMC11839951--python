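"""Synthetic session generator.

Every downstream stage of the pipeline is validated against sessions
drawn from a known generative model: a latent Markov chain over
oscillation states drives band-specific LFP power, state-coupled
behavior traces, state-dependent (gamma-renewal) spiking with a shared
latent factor, and state-switched encoding weights.  The movie surrogate
is spatio-temporally filtered noise quantized to 8 bits.

The statistical structure mirrors the assumptions of the analysis: a
3-state chain with a gamma-dominant, an intermediate, and a
theta-dominant state; diagonal-Gaussian HMM emissions; Poisson-like
single-unit variability with weak shared co-fluctuations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .lfp import DEFAULT_BANDS, FrequencyBand, butter_bank

__all__ = [
    "GroundTruthHmm",
    "SyntheticSession",
    "default_ground_truth",
    "stationary_distribution",
    "simulate_state_sequence",
    "simulate_lfp_and_behavior",
    "simulate_spikes",
    "simulate_movie",
    "generate_targets",
    "simulate_encoding_session",
    "simulate_session",
]

BEHAVIOR_NAMES = ("running", "pupil", "face_motion", "limb_speed", "tail_speed")


@dataclass
class GroundTruthHmm:
    """Generator parameters for a diagonal-Gaussian hidden Markov model.

    ``band_power_profile`` (n_states x n_bands) gives the relative
    amplitude of each analysis band in each state and is used both to
    emit HMM observations (when the observation space is band envelopes)
    and to synthesize band-limited LFP.
    """

    transition_matrix: np.ndarray
    emission_means: np.ndarray  # (n_states, n_obs)
    emission_scales: np.ndarray  # (n_states, n_obs), > 0
    band_power_profile: np.ndarray | None = None  # (n_states, n_bands), > 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.emission_means = np.atleast_2d(np.asarray(self.emission_means, dtype=float))
        self.emission_scales = np.atleast_2d(np.asarray(self.emission_scales, dtype=float))
        T = self.transition_matrix
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] < 1:
            raise ValueError("transition matrix must be square, n_states >= 1")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must be non-negative and sum to 1 (tol 1e-12)")
        if self.emission_means.shape != self.emission_scales.shape:
            raise ValueError("emission means/scales shape mismatch")
        if self.emission_means.shape[0] != T.shape[0]:
            raise ValueError("one emission row per state required")
        if np.any(self.emission_scales <= 0):
            raise ValueError("emission scales must be strictly positive")
        if self.band_power_profile is not None:
            self.band_power_profile = np.atleast_2d(
                np.asarray(self.band_power_profile, dtype=float)
            )
            if self.band_power_profile.shape[0] != T.shape[0]:
                raise ValueError("band_power_profile needs one row per state")
            if np.any(self.band_power_profile <= 0):
                raise ValueError("band_power_profile must be strictly positive")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.emission_means.shape[1]


def default_ground_truth(
    n_channels: int = 3,
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS,
    gamma_contrast: float = 3.0,
    stay: float = 0.97,
) -> GroundTruthHmm:
    """The canonical 3-state generator used across the test-bench.

    State 0 is gamma-dominant (the high-frequency state), state 1 is
    flat (intermediate), state 2 is theta-dominant (low-frequency).
    Observations are per-(channel, band) envelope means.
    """
    n_states, n_bands = 3, len(bands)
    T = np.full((n_states, n_states), (1 - stay) / (n_states - 1))
    np.fill_diagonal(T, stay)
    profile = np.ones((n_states, n_bands))
    # bands ordered theta, beta, low gamma, high gamma
    profile[0, 2:] = gamma_contrast
    profile[2, 0] = gamma_contrast
    means = np.tile(profile, (1, n_channels))
    scales = np.full_like(means, 0.25)
    return GroundTruthHmm(T, means, scales, profile)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(
    hmm: GroundTruthHmm, n_bins: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and diagonal-Gaussian observations.

    Returns ``(labels, observations)`` with ``labels`` in
    ``[0, n_states)`` and ``observations`` of shape ``(n_bins, n_obs)``.
    The initial state is drawn from the stationary distribution.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    T = hmm.transition_matrix
    cum = T.cumsum(axis=1)
    pi = stationary_distribution(T)
    labels = np.empty(n_bins, dtype=np.int64)
    u = rng.random(n_bins)
    s = int(np.searchsorted(pi.cumsum(), u[0]))
    labels[0] = s
    for i in range(1, n_bins):
        s = int(np.searchsorted(cum[s], u[i]))
        labels[i] = s
    obs = hmm.emission_means[labels] + rng.standard_normal(
        (n_bins, hmm.n_obs)
    ) * hmm.emission_scales[labels]
    return labels, obs


def simulate_lfp_and_behavior(
    states: np.ndarray,
    profile: np.ndarray,
    coupling: float,
    seed: int,
    fs: float = 1250.0,
    n_channels: int = 3,
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS,
    bin_s: float = 0.03,
    behavior_names: tuple[str, ...] = BEHAVIOR_NAMES,
    behavior_noise_sd: float = 1.0,
    broadband_sd: float = 0.05,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Band-limited LFP plus state-coupled behavior traces.

    Each channel is a sum over bands of white noise filtered through the
    same Butterworth bank used by the analysis, with the per-band
    amplitude following the active state's ``profile`` row (piecewise
    constant at ``bin_s`` resolution).  Behavior traces at 30 Hz are
    state-dependent mean shifts scaled by ``coupling`` plus unit-variance
    Gaussian noise.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    states = np.asarray(states, dtype=int)
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    if profile.shape[1] != len(bands):
        raise ValueError("profile must cover all analysis bands")
    rng = np.random.default_rng(seed)
    n_bins = states.size
    n_samp = int(round(n_bins * bin_s * fs))
    # per-sample state via the sample -> bin mapping (robust to non-integer
    # samples-per-bin)
    sample_bin = np.minimum((np.arange(n_samp) / (bin_s * fs)).astype(int), n_bins - 1)
    amp = profile[states][sample_bin]  # (n_samp, n_bands)
    sos_bank = butter_bank(bands, fs)
    lfp = np.empty((n_channels, n_samp))
    for ci in range(n_channels):
        acc = rng.standard_normal(n_samp) * broadband_sd
        for bi, sos in enumerate(sos_bank):
            carrier = _signal.sosfiltfilt(sos, rng.standard_normal(n_samp))
            sd = carrier.std()
            if sd > 0:
                carrier /= sd
            acc = acc + amp[:, bi] * carrier
        lfp[ci] = acc
    # behavior: distinct per-trace state means so every trace is informative
    n_states = profile.shape[0]
    base = np.linspace(1.0, 2.0, len(behavior_names))
    state_means = np.outer(np.arange(n_states) - (n_states - 1) / 2.0, base)
    behavior = {}
    for j, name in enumerate(behavior_names):
        behavior[name] = (
            coupling * state_means[states, j]
            + rng.standard_normal(n_bins) * behavior_noise_sd
        )
    return lfp, behavior


def _renewal_train(rng, cum_intensity: np.ndarray, t_grid: np.ndarray, shape: float) -> np.ndarray:
    """Sample one renewal train by time rescaling.

    ``cum_intensity`` is the cumulative intensity on ``t_grid``; unit-rate
    gamma(shape, 1/shape) interarrival times in operational time are
    mapped back through its inverse.
    """
    total = cum_intensity[-1]
    if total <= 0:
        return np.empty(0)
    n_draw = max(16, int(total + 4 * np.sqrt(total) + 8))
    taus = np.cumsum(rng.gamma(shape, 1.0 / shape, size=n_draw))
    while taus[-1] < total:
        extra = np.cumsum(rng.gamma(shape, 1.0 / shape, size=n_draw)) + taus[-1]
        taus = np.concatenate([taus, extra])
    taus = taus[taus < total]
    return np.interp(taus, cum_intensity, t_grid)


def simulate_spikes(
    states: np.ndarray,
    rates: np.ndarray,
    renewal_shape: float = 1.0,
    shared_factor_strength: float = 0.0,
    n_trials: int = 1,
    seed: int = 0,
    bin_s: float = 0.03,
) -> list[list[np.ndarray]]:
    """Trial-structured spike trains with state-dependent rates.

    Each unit fires as a gamma-renewal process (``renewal_shape=1`` is
    Poisson) whose instantaneous rate is ``rates[u, state(t)]`` modulated
    by a common Gaussian latent factor: the log-rate gains
    ``g * z(t) - g**2 / 2`` with ``z`` standard normal per (trial, bin),
    shared across units, so the mean rate is preserved.  The same state
    path applies to every trial (repeated-viewing structure).

    Returns ``spikes[u][trial]`` arrays of spike times (s) within the trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if renewal_shape <= 0:
        raise ValueError("renewal_shape must be > 0")
    if shared_factor_strength < 0:
        raise ValueError("shared_factor_strength must be >= 0")
    states = np.asarray(states, dtype=int)
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    n_units = rates.shape[0]
    n_bins = states.size
    rng = np.random.default_rng(seed)
    g = shared_factor_strength
    t_edges = np.arange(n_bins + 1) * bin_s
    spikes: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    for tr in range(n_trials):
        z = rng.standard_normal(n_bins)
        mod = np.exp(g * z - g * g / 2.0)
        for u in range(n_units):
            r = rates[u, states] * mod
            cum = np.concatenate([[0.0], np.cumsum(r * bin_s)])
            spikes[u].append(_renewal_train(rng, cum, t_edges, renewal_shape))
    return spikes


def simulate_movie(
    n_frames: int,
    shape: tuple[int, int] = (96, 152),
    seed: int = 0,
    spatial_sigma: float = 3.0,
    temporal_sigma: float = 2.0,
) -> np.ndarray:
    """Spatio-temporally filtered noise quantized to uint8 frames."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_frames, *shape))
    x = gaussian_filter(x, sigma=(temporal_sigma, spatial_sigma, spatial_sigma))
    lo, hi = x.min(), x.max()
    if hi > lo:
        x = (x - lo) / (hi - lo)
    return np.clip(np.round(x * 255), 0, 255).astype(np.uint8)


def generate_targets(
    X: np.ndarray,
    states: np.ndarray,
    weights: np.ndarray,
    noise_sd: float = 0.0,
    link: str = "identity",
    intercept: float | np.ndarray = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Targets from the state-switched encoding model.

    ``identity``: ``y = X w_s + intercept + noise``;
    ``log``: ``y ~ Poisson(exp(X w_s + intercept))``.
    ``weights`` has shape (n_states, n_features).
    """
    X = np.asarray(X, dtype=float)
    states = np.asarray(states, dtype=int)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if weights.shape[1] != X.shape[1]:
        raise ValueError(
            f"weight dimension {weights.shape[1]} does not match design "
            f"columns {X.shape[1]}"
        )
    if states.size != X.shape[0]:
        raise ValueError("states length must match design rows")
    eta = np.einsum("ij,ij->i", X, weights[states]) + intercept
    rng = np.random.default_rng(seed)
    if link == "identity":
        y = eta
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, size=eta.shape)
        return y
    if link == "log":
        return rng.poisson(np.exp(eta)).astype(float)
    raise ValueError(f"unknown link {link!r}")


@dataclass
class SyntheticSession:
    """A complete synthetic session with ground truth attached.

    All streams cover the same time span: ``true_states`` at 30 ms bins,
    LFP at ``lfp_fs``, behavior and movie at the bin rate.
    """

    lfp: np.ndarray  # (n_channels, n_samples)
    lfp_fs: float
    lfp_channel_meta: list[dict]
    spikes: list[list[np.ndarray]]  # [unit][trial] spike times (s)
    units: pd.DataFrame
    behavior: dict[str, np.ndarray]
    movie: np.ndarray  # (n_frames, H, W) uint8, tiled over trials
    true_states: np.ndarray  # per 30 ms bin
    true_weights: dict | None = None
    hmm: GroundTruthHmm | None = None
    bin_s: float = 0.03
    n_trials: int = 1
    trial_len_bins: int = 0
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.true_states.size

    def validate(self) -> None:
        if self.movie.min() < 0 or self.movie.max() > 255:
            raise ValueError("movie frames must lie in [0, 255]")
        dur_bins = self.n_bins * self.bin_s
        dur_lfp = self.lfp.shape[1] / self.lfp_fs
        if abs(dur_bins - dur_lfp) > self.bin_s:
            raise ValueError("LFP and state streams cover different spans")
        for u, trials in enumerate(self.spikes):
            for st in trials:
                if st.size > 1 and np.any(np.diff(st) <= 0):
                    raise ValueError(f"unit {u}: spike times not strictly increasing")

    def save(self, path: str | Path) -> None:
        """Write the bundle: NPZ arrays + units.csv + JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {
            "lfp": self.lfp,
            "movie": self.movie,
            "true_states": self.true_states,
        }
        for name, tr in self.behavior.items():
            arrays[f"behavior/{name}"] = tr
        for u, trials in enumerate(self.spikes):
            for t, st in enumerate(trials):
                arrays[f"spikes/{u}/{t}"] = st
        np.savez_compressed(path / "arrays.npz", **arrays)
        self.units.to_csv(path / "units.csv", index=False)
        sidecar = {
            "seed": int(self.seed),
            "bin_s": self.bin_s,
            "lfp_fs": self.lfp_fs,
            "n_trials": int(self.n_trials),
            "trial_len_bins": int(self.trial_len_bins),
            "n_units": len(self.spikes),
            "params": self.params,
            "lfp_channel_meta": self.lfp_channel_meta,
        }
        (path / "session.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticSession":
        path = Path(path)
        side = json.loads((path / "session.json").read_text())
        with np.load(path / "arrays.npz") as z:
            lfp = z["lfp"]
            movie = z["movie"]
            true_states = z["true_states"]
            behavior = {
                k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("behavior/")
            }
            spikes: list[list[np.ndarray]] = [
                [] for _ in range(side["n_units"])
            ]
            for k in z.files:
                if k.startswith("spikes/"):
                    _, u, t = k.split("/")
                    spikes[int(u)].append((int(t), z[k]))
            spikes = [[st for _, st in sorted(tr)] for tr in spikes]
        units = pd.read_csv(path / "units.csv")
        return cls(
            lfp=lfp,
            lfp_fs=side["lfp_fs"],
            lfp_channel_meta=side["lfp_channel_meta"],
            spikes=spikes,
            units=units,
            behavior=behavior,
            movie=movie,
            true_states=true_states,
            bin_s=side["bin_s"],
            n_trials=side["n_trials"],
            trial_len_bins=side["trial_len_bins"],
            seed=side["seed"],
            params=side["params"],
        )


def _default_units_table(n_units: int, rng: np.random.Generator) -> pd.DataFrame:
    areas = ["V1", "LM", "RL", "AL", "PM", "AM"]
    layers = ["L2/3", "L4", "L5/6"]
    return pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "area": [areas[i % len(areas)] for i in range(n_units)],
            "layer": [layers[i % len(layers)] for i in range(n_units)],
            "cell_class": ["RS" if i % 4 else "FS" for i in range(n_units)],
            "rf_x": rng.uniform(25, 95, n_units),
            "rf_y": rng.uniform(25, 70, n_units),
            "presence_ratio": rng.uniform(0.96, 1.0, n_units),
            "isi_violations": rng.uniform(0.0, 0.3, n_units),
            "amplitude_cutoff": rng.uniform(0.0, 0.08, n_units),
        }
    )


def simulate_session(
    duration_s: float = 300.0,
    n_units: int = 40,
    n_trials: int | None = None,
    trial_len_s: float = 30.0,
    seed: int = 0,
    coupling: float = 1.0,
    gamma_contrast: float = 3.0,
    renewal_shape: float = 1.0,
    shared_factor_strength: float = 0.2,
    lfp_fs: float = 1250.0,
    n_channels: int = 3,
    movie_shape: tuple[int, int] = (96, 152),
    rate_lo: float = 2.0,
    rate_hi: float = 12.0,
) -> SyntheticSession:
    """Assemble a full synthetic session.

    The session is split into ``n_trials`` repeats of a ``trial_len_s``
    movie clip; the latent state path runs continuously across trials.
    Per-unit per-state rates are drawn log-uniformly in
    ``[rate_lo, rate_hi]`` spk/s.
    """
    bin_s = 0.03
    trial_len_bins = int(round(trial_len_s / bin_s))
    if n_trials is None:
        n_trials = max(1, int(round(duration_s / trial_len_s)))
    n_bins = n_trials * trial_len_bins
    gt = default_ground_truth(n_channels=n_channels, gamma_contrast=gamma_contrast)
    rng = np.random.default_rng(seed)
    labels, _ = simulate_state_sequence(gt, n_bins, seed=int(rng.integers(2**31)))
    lfp, behavior = simulate_lfp_and_behavior(
        labels,
        gt.band_power_profile,
        coupling,
        seed=int(rng.integers(2**31)),
        fs=lfp_fs,
        n_channels=n_channels,
    )
    rates = np.exp(rng.uniform(np.log(rate_lo), np.log(rate_hi), size=(n_units, 3)))
    # state-dependent modulation: spread rates across states
    rates *= rng.uniform(0.6, 1.6, size=(n_units, 3))
    # spike trains per trial; states for a trial are the session path slice
    spike_rngseed = int(rng.integers(2**31))
    spikes: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    srng = np.random.default_rng(spike_rngseed)
    for tr in range(n_trials):
        sl = labels[tr * trial_len_bins : (tr + 1) * trial_len_bins]
        block = simulate_spikes(
            sl,
            rates,
            renewal_shape=renewal_shape,
            shared_factor_strength=shared_factor_strength,
            n_trials=1,
            seed=int(srng.integers(2**31)),
            bin_s=bin_s,
        )
        for u in range(n_units):
            spikes[u].append(block[u][0])
    movie = simulate_movie(
        trial_len_bins, shape=movie_shape, seed=int(rng.integers(2**31))
    )
    units = _default_units_table(n_units, rng)
    channel_meta = [
        {"area": "V1", "layer": ["L2/3", "L4", "L5/6"][i % 3]} for i in range(n_channels)
    ]
    sess = SyntheticSession(
        lfp=lfp,
        lfp_fs=lfp_fs,
        lfp_channel_meta=channel_meta,
        spikes=spikes,
        units=units,
        behavior=behavior,
        movie=movie,
        true_states=labels,
        hmm=gt,
        bin_s=bin_s,
        n_trials=n_trials,
        trial_len_bins=trial_len_bins,
        seed=seed,
        params={
            "coupling": coupling,
            "gamma_contrast": gamma_contrast,
            "renewal_shape": renewal_shape,
            "shared_factor_strength": shared_factor_strength,
            "rates_lo_hi": [rate_lo, rate_hi],
        },
    )
    sess.true_weights = {"rates": rates}
    sess.validate()
    return sess


def simulate_encoding_session(
    true_weights: np.ndarray,
    states: np.ndarray,
    X: np.ndarray,
    noise_sd: float = 0.0,
    link: str = "identity",
    seed: int | None = None,
) -> dict:
    """Targets plus ground truth for encoding-model recovery tests.

    Thin assembly over :func:`generate_targets`: returns a dict with the
    design, per-state ``true_weights``, the state path and the target.
    """
    y = generate_targets(X, states, true_weights, noise_sd=noise_sd, link=link, seed=seed)
    return {
        "X": np.asarray(X, dtype=float),
        "states": np.asarray(states, dtype=int),
        "true_weights": np.atleast_2d(np.asarray(true_weights, dtype=float)),
        "y": y,
        "link": link,
        "noise_sd": noise_sd,
    }
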