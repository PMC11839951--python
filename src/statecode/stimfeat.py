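"""Per-frame stimulus features.

Six scalar statistics per movie frame: intensity (mean), contrast (SD),
Pearson kurtosis, pixel-value entropy in bits, temporal energy (summed
absolute frame difference) and the Canny edge fraction.  The Canny
detector follows the classical pipeline: 5x5 Gaussian smoothing, Sobel
gradients, non-maximum suppression with directions quantized to
{0, 45, 90, 135} degrees, and double-threshold hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CannyConfig",
    "canny_edges",
    "frame_features",
    "frame_feature_table",
]


@dataclass(frozen=True)
class CannyConfig:
    """Hysteresis thresholds for the Canny detector.

    ``None`` thresholds are chosen per frame: ``high`` by Otsu's method
    on the gradient-magnitude histogram, ``low = high / 2``.
    """

    low: float | None = None
    high: float | None = None
    gaussian_sigma: float = 1.0  # of the 5x5 smoothing kernel

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and not 0 <= self.low < self.high:
            raise ValueError("need 0 <= low < high")


def _gaussian_kernel_5x5(sigma: float) -> np.ndarray:
    ax = np.arange(-2, 3, dtype=float)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a 1-D sample (maximizes between-class variance)."""
    v = values.ravel()
    hi = v.max()
    if hi <= 0:
        return 0.0
    hist, edges = np.histogram(v, bins=nbins, range=(0.0, hi))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -1
    return float(centers[int(np.argmax(between))])


def canny_edges(
    frame: np.ndarray, config: CannyConfig = CannyConfig()
) -> tuple[np.ndarray, float]:
    """Binary edge map and edge fraction of a grayscale frame.

    Steps: 5x5 Gaussian smoothing; Sobel gradients Gx, Gy; magnitude
    sqrt(Gx^2 + Gy^2) and direction atan2(Gy, Gx) quantized to four
    bins; non-maximum suppression along the gradient direction (ties
    broken toward a single surviving pixel: strictly greater than one
    neighbor, at least equal to the other); hysteresis keeps weak edges
    only when connected to a sure edge.  The fraction is the mean of the
    binary map.
    """
    f = np.asarray(frame, dtype=float)
    if f.ndim != 2 or min(f.shape) < 5:
        raise ValueError("frame must be 2-D and at least 5 x 5 pixels")
    smoothed = ndimage.convolve(f, _gaussian_kernel_5x5(config.gaussian_sigma), mode="nearest")
    gx = ndimage.convolve(smoothed, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(smoothed, _SOBEL_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    if not mag.any():
        return np.zeros_like(f, dtype=bool), 0.0
    theta = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    dbin = np.zeros(f.shape, dtype=int)  # 0: 0 deg, 1: 45, 2: 90, 3: 135
    dbin[(theta >= 22.5) & (theta < 67.5)] = 1
    dbin[(theta >= 67.5) & (theta < 112.5)] = 2
    dbin[(theta >= 112.5) & (theta < 157.5)] = 3

    def shifted(arr, dy, dx):
        out = np.zeros_like(arr)
        ys = slice(max(dy, 0), arr.shape[0] + min(dy, 0))
        xs = slice(max(dx, 0), arr.shape[1] + min(dx, 0))
        yd = slice(max(-dy, 0), arr.shape[0] + min(-dy, 0))
        xd = slice(max(-dx, 0), arr.shape[1] + min(-dx, 0))
        out[yd, xd] = arr[ys, xs]
        return out

    # neighbor offsets along the gradient direction per bin
    offsets = {0: (0, 1), 1: (-1, 1), 2: (-1, 0), 3: (-1, -1)}
    nms = np.zeros(f.shape, dtype=bool)
    for b, (dy, dx) in offsets.items():
        n1 = shifted(mag, dy, dx)
        n2 = shifted(mag, -dy, -dx)
        keep = (mag > n1) & (mag >= n2)
        nms |= keep & (dbin == b)
    nms_mag = np.where(nms, mag, 0.0)
    high = config.high if config.high is not None else _otsu_threshold(mag)
    low = config.low if config.low is not None else high / 2.0
    strong = nms_mag > high
    weak_or_strong = nms_mag > low
    if not strong.any():
        return np.zeros_like(f, dtype=bool), 0.0
    lab, _ = ndimage.label(weak_or_strong, structure=np.ones((3, 3)))
    keep_labels = np.unique(lab[strong])
    edge_map = np.isin(lab, keep_labels) & weak_or_strong
    return edge_map, float(edge_map.mean())


def frame_features(
    frame: np.ndarray,
    previous_frame: np.ndarray | None = None,
    canny_config: CannyConfig = CannyConfig(),
) -> dict[str, float]:
    """Six scalar features of one frame (pixel values in [0, 255]).

    ``kurtosis`` is Pearson (non-excess), undefined for constant frames;
    ``energy`` needs a previous frame and is ``nan`` otherwise.
    """
    f = np.asarray(frame, dtype=float)
    if f.min() < 0 or f.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    mu = float(f.mean())
    sd = float(f.std())
    if sd > 0:
        kurt = float(np.mean((f - mu) ** 4) / sd**4)
    else:
        kurt = float("nan")
    p = np.bincount(np.round(f).astype(int).ravel(), minlength=256) / f.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if previous_frame is None:
        energy = float("nan")
    else:
        energy = float(np.abs(f - np.asarray(previous_frame, dtype=float)).sum())
    _, edge_frac = canny_edges(f, canny_config)
    return {
        "intensity": mu,
        "contrast": sd,
        "kurtosis": kurt,
        "entropy": entropy,
        "energy": energy,
        "edges": edge_frac,
    }


def frame_feature_table(
    movie: np.ndarray, canny_config: CannyConfig = CannyConfig()
) -> pd.DataFrame:
    """Feature rows for every frame of a movie (frames x H x W).

    The first frame's energy is ``nan`` (no predecessor); design-matrix
    assembly imputes it as zero.
    """
    rows = []
    prev = None
    for i in range(movie.shape[0]):
        feats = frame_features(movie[i], prev, canny_config)
        feats["frame_idx"] = i
        rows.append(feats)
        prev = movie[i]
    df = pd.DataFrame(rows)
    return df[["frame_idx", "intensity", "contrast", "kurtosis", "entropy", "energy", "edges"]]
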