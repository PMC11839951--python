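"""Spectral preprocessing of local field potentials.

Band-limited envelopes (the observations handed to the oscillation-state
HMM), z-scored spectrograms, current source density (CSD) maps, and
CSD-based cortical layer assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

__all__ = [
    "FrequencyBand",
    "DEFAULT_BANDS",
    "EnvelopeMatrix",
    "CsdMap",
    "LayerAssignment",
    "band_envelopes",
    "zscored_spectrogram",
    "compute_csd",
    "assign_layers",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )


#: Analysis bands: theta, beta, low gamma, high gamma.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("theta", 3.0, 8.0),
    FrequencyBand("beta", 10.0, 30.0),
    FrequencyBand("low_gamma", 30.0, 50.0),
    FrequencyBand("high_gamma", 50.0, 80.0),
)


@dataclass
class EnvelopeMatrix:
    """Band envelopes averaged in non-overlapping time bins.

    ``values`` has shape ``(n_channels, n_bands, n_bins)``; bin ``k``
    covers the half-open interval ``[k * bin_s, (k + 1) * bin_s)``
    anchored at the start of the recording.
    """

    values: np.ndarray
    bands: tuple[FrequencyBand, ...]
    bin_s: float = 0.03
    channel_meta: list[dict] | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def to_observations(self) -> np.ndarray:
        """Stack to an HMM observation matrix of shape (n_bins, n_channels * n_bands)."""
        n_ch, n_bands, n_bins = self.values.shape
        return self.values.reshape(n_ch * n_bands, n_bins).T

    def band_index(self) -> np.ndarray:
        """Band id of each column of :meth:`to_observations`."""
        n_ch, n_bands, _ = self.values.shape
        return np.tile(np.arange(n_bands), n_ch)


def _butter_sos(band: FrequencyBand, fs: float, order: int = 11) -> np.ndarray:
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is at or above Nyquist "
            f"({nyq} Hz)"
        )
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def butter_bank(
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS, fs: float = 1250.0, order: int = 11
) -> list[np.ndarray]:
    """Second-order-section Butterworth band-pass bank (zero-phase use intended)."""
    return [_butter_sos(b, fs, order) for b in bands]


def band_envelopes(
    lfp: np.ndarray,
    fs: float,
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS,
    bin_s: float = 0.03,
    order: int = 11,
    pad_s: float = 1.0,
    channel_meta: list[dict] | None = None,
) -> EnvelopeMatrix:
    """Band-pass, Hilbert-envelope and bin each LFP channel.

    For every band the signal is filtered with a zero-phase (forward-
    backward) Butterworth band-pass of the given design order, the
    magnitude of the analytic signal is taken, and the result is averaged
    within non-overlapping ``bin_s`` windows.  ``pad_s`` seconds of
    reflection padding are applied around the Hilbert transform to
    suppress edge transients and trimmed afterwards.

    Parameters
    ----------
    lfp : array, shape (n_channels, n_samples) or (n_samples,)
        Raw LFP traces.
    fs : float
        Sampling rate in Hz.  Must exceed twice the highest band edge.

    Returns
    -------
    EnvelopeMatrix
        Non-negative envelope values, ``(n_channels, n_bands, n_bins)``
        with ``n_bins = floor(duration / bin_s)``.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if not np.all(np.isfinite(lfp)):
        raise ValueError("LFP contains non-finite samples")
    n_ch, n_samp = lfp.shape
    sos_bank = butter_bank(bands, fs, order)
    n_bins = int(np.floor(n_samp / fs / bin_s))
    # bin edges in samples; handles non-integer samples-per-bin exactly
    edges = np.floor(np.arange(n_bins + 1) * bin_s * fs).astype(int)
    seg_len = np.diff(edges)
    pad = min(int(round(pad_s * fs)), n_samp - 1)
    out = np.empty((n_ch, len(bands), n_bins))
    for ci in range(n_ch):
        for bi, sos in enumerate(sos_bank):
            filt = signal.sosfiltfilt(sos, lfp[ci])
            if pad > 0:
                padded = np.concatenate(
                    [filt[pad:0:-1], filt, filt[-2 : -pad - 2 : -1]]
                )
            else:
                padded = filt
            env = np.abs(signal.hilbert(padded))
            if pad > 0:
                env = env[pad : pad + n_samp]
            out[ci, bi] = np.add.reduceat(env[: edges[-1]], edges[:-1]) / seg_len
    return EnvelopeMatrix(out, tuple(bands), bin_s, channel_meta)


def zscored_spectrogram(
    x: np.ndarray, fs: float, window_s: float = 0.8, overlap_s: float = 0.4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """STFT power of one channel, z-scored independently per frequency row.

    Uses a Hann window of ``window_s`` seconds with ``overlap_s`` seconds
    of overlap between consecutive windows.

    Returns ``(freqs, times, z)`` where ``z`` is frequency x time.
    """
    x = np.asarray(x, dtype=float)
    if overlap_s >= window_s:
        raise ValueError(f"overlap ({overlap_s}) must be smaller than window ({window_s})")
    nperseg = int(round(window_s * fs))
    if nperseg > x.size:
        raise ValueError("window longer than the signal")
    noverlap = int(round(overlap_s * fs))
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    mu = sxx.mean(axis=1, keepdims=True)
    sd = sxx.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return freqs, times, (sxx - mu) / sd


@dataclass
class CsdMap:
    """Current source density map: spatially smoothed potentials and their
    second spatial derivative (sinks negative)."""

    smoothed: np.ndarray  # depth x time, s-bar
    csd: np.ndarray  # depth x time, D
    h: float
    sigmas: tuple[float, float] = (1.0, 2.0)
    display: np.ndarray | None = None  # Gaussian-smoothed CSD for figures


def compute_csd(
    evoked: np.ndarray,
    h: float = 1.0,
    sigmas: tuple[float, float] = (1.0, 2.0),
    smooth_display: bool = False,
) -> CsdMap:
    """Second-spatial-derivative CSD of a depth x time evoked LFP.

    The uppermost and lowermost traces are duplicated, the potentials are
    smoothed across sites, ``s_bar(r) = (s(r+h) + 2 s(r) + s(r-h)) / 4``,
    and the CSD is the discrete second spatial derivative
    ``D = (s_bar(r+h) - 2 s_bar(r) + s_bar(r-h)) / h**2``.  Boundary rows
    of ``D`` replicate the nearest interior row so the output keeps one
    row per input channel.
    """
    s = np.asarray(evoked, dtype=float)
    if s.ndim != 2 or s.shape[0] < 3:
        raise ValueError("need at least 3 depth channels (depth x time array)")
    ext = np.vstack([s[:1], s, s[-1:]])
    sbar = (ext[2:] + 2.0 * ext[1:-1] + ext[:-2]) / 4.0
    sext = np.vstack([sbar[:1], sbar, sbar[-1:]])
    csd = (sext[2:] - 2.0 * sext[1:-1] + sext[:-2]) / h**2
    # rows within 2 channels of a boundary inherit the duplication bias of
    # s-bar; replace them with the nearest unbiased interior row
    n = s.shape[0]
    if n >= 5:
        csd[0] = csd[1] = csd[2]
        csd[-1] = csd[-2] = csd[-3]
    display = gaussian_filter(csd, sigma=sigmas) if smooth_display else None
    return CsdMap(sbar, csd, h, sigmas, display)


@dataclass
class LayerAssignment:
    """Per-channel cortical layer labels derived from the CSD sink."""

    sink_found: bool
    center: int | None = None
    sink_time_index: int | None = None
    labels: list[str] = field(default_factory=list)

    def layer_channels(self, layer: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == layer)


def assign_layers(
    csd: CsdMap | np.ndarray,
    times: np.ndarray,
    stim_onset: float,
    sink_window_s: float = 0.1,
    threshold_sd: float = 2.0,
    l4_halfwidth: int = 8,
) -> LayerAssignment:
    """Locate the input layer from the earliest CSD sink and label layers.

    The earliest channel whose CSD drops below ``median - threshold_sd *
    robust SD`` of the pre-stimulus baseline within ``sink_window_s`` of
    stimulus onset becomes the L4 center; ``center +- l4_halfwidth``
    channels are L4, channels above are L2/3 and channels below are L5/6.
    If no channel crosses the threshold the result reports
    ``sink_found=False`` instead of defaulting silently.
    """
    d = csd.csd if isinstance(csd, CsdMap) else np.asarray(csd, dtype=float)
    times = np.asarray(times, dtype=float)
    if d.shape[1] != times.size:
        raise ValueError("times length must match the CSD time axis")
    base = d[:, times < stim_onset]
    if base.size == 0:
        raise ValueError("CSD must include a pre-onset baseline")
    med = np.median(base)
    mad = np.median(np.abs(base - med))
    robust_sd = 1.4826 * mad if mad > 0 else base.std() or 1.0
    thresh = med - threshold_sd * robust_sd
    in_win = (times > stim_onset) & (times <= stim_onset + sink_window_s)
    win_idx = np.flatnonzero(in_win)
    below = d[:, win_idx] < thresh
    if not below.any():
        return LayerAssignment(sink_found=False)
    # first time index with any crossing; among simultaneous crossings the
    # deepest deflection wins
    t_first = np.flatnonzero(below.any(axis=0))[0]
    chans = np.flatnonzero(below[:, t_first])
    center = int(chans[np.argmin(d[chans, win_idx[t_first]])])
    n_ch = d.shape[0]
    labels = []
    for c in range(n_ch):
        if abs(c - center) <= l4_halfwidth:
            labels.append("L4")
        elif c < center:
            labels.append("L2/3")
        else:
            labels.append("L5/6")
    return LayerAssignment(True, center, int(win_idx[t_first]), labels)


def envelopes_to_csv(env: EnvelopeMatrix) -> "object":
    """Long-format DataFrame view of an EnvelopeMatrix (channel, band, bin, value)."""
    import pandas as pd

    n_ch, n_bands, n_bins = env.values.shape
    ch, bd, bn = np.meshgrid(
        np.arange(n_ch), np.arange(n_bands), np.arange(n_bins), indexing="ij"
    )
    return pd.DataFrame(
        {
            "channel": ch.ravel(),
            "band": [env.bands[i].name for i in bd.ravel()],
            "bin": bn.ravel(),
            "value": env.values.ravel(),
        }
    )
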