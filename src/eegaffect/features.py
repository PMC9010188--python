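"""Band-wise differential-entropy features, LDS smoothing and feature imaging.

The feature chain is: band-filter a preprocessed recording into the five
canonical bands, compute the Gaussian differential entropy of each
non-overlapping window, smooth each (channel, band) sequence with a
random-walk state-space smoother, lay the channels-x-windows-x-bands tensor
out as a 2-D plane and resample it to a 224 x 224 min-max standardized
image for the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import ndimage, signal

from .core import BAND_NAMES, CANONICAL_BANDS, N_CHANNELS, BandDefinition

__all__ = [
    "VARIANCE_FLOOR",
    "IMAGE_SHAPE",
    "DETensor",
    "FeatureImage",
    "LDSConfig",
    "band_sos",
    "differential_entropy",
    "extract_de_tensor",
    "lds_smooth",
    "smooth_tensor",
    "minmax_standardize",
    "tensor_to_plane",
    "to_feature_image",
    "featurize_recording",
]

#: Variance floor applied before the log so degenerate windows never map to -inf.
VARIANCE_FLOOR = 1e-12

#: Classifier input grid.
IMAGE_SHAPE = (224, 224)

#: Number of DE windows in a pipeline-conformant tensor.
CONFORMANT_WINDOWS = 180


@dataclass
class DETensor:
    """Channels x windows x bands differential-entropy values (nats)."""

    values: np.ndarray
    window_length: float
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.values.shape[2] != len(self.bands):
            raise ValueError(
                f"band axis has length {self.values.shape[2]}, expected {len(self.bands)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DE tensor contains non-finite values")
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_pipeline_conformant(self) -> bool:
        return self.shape == (N_CHANNELS, CONFORMANT_WINDOWS, len(CANONICAL_BANDS))


@dataclass
class FeatureImage:
    """A 224 x 224 grid in [0, 1] plus the pre-standardization extrema."""

    values: np.ndarray
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != IMAGE_SHAPE:
            raise ValueError(f"image must be {IMAGE_SHAPE}, got {self.values.shape}")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("image values must lie in [0, 1]")


@dataclass
class LDSConfig:
    """Configuration of the feature-sequence smoother.

    ``window`` (seconds, i.e. windows at the 1 s DE step) sets the smoothing
    scale. Noise variances may be fixed numbers or ``"auto"``, in which case
    the observation noise is estimated from first differences and the state
    noise is ``obs / window**2``. ``method`` selects the random-walk
    Kalman/RTS smoother or the documented moving-average fallback.
    """

    window: float = 20.0
    state_noise: Union[float, str] = "auto"
    obs_noise: Union[float, str] = "auto"
    method: str = "kalman"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.method not in ("kalman", "moving_average"):
            raise ValueError(f"unknown smoothing method {self.method!r}")


def band_sos(low: float, high: float, sample_rate: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the Butterworth bandpass for one band.

    The upper edge is clipped just below Nyquist so the canonical gamma band
    remains designable at the 100 Hz lower limit of the rate precondition.
    """
    nyq = sample_rate / 2.0
    high = min(high, 0.999 * nyq)
    if not (0 < low < high):
        raise ValueError(f"cannot design band {low}-{high} Hz at rate {sample_rate}")
    return signal.butter(order, [low, high], btype="bandpass", fs=sample_rate, output="sos")


def differential_entropy(samples: np.ndarray) -> float:
    """Gaussian differential entropy of a signal window, in nats.

    Uses the closed form ``0.5 * log(2*pi*e*var)`` with the plug-in (ddof=0)
    variance estimate; the variance is floored at :data:`VARIANCE_FLOOR` so a
    constant window yields a finite documented floor value instead of -inf.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"window needs >= 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    var = max(float(np.var(x)), VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def _window_de(band_filtered: np.ndarray, samples_per_window: int) -> np.ndarray:
    """DE per non-overlapping window for a channels x samples band signal."""
    c, n = band_filtered.shape
    n_win = n // samples_per_window
    windows = band_filtered[:, : n_win * samples_per_window].reshape(c, n_win, samples_per_window)
    var = np.maximum(windows.var(axis=2), VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def extract_de_tensor(rec, window_length: float = 1.0) -> DETensor:
    """Band-filter a recording and compute DE per channel, window and band.

    The recording is expected preprocessed (200 Hz, <= 75 Hz content) and its
    duration must be an exact multiple of ``window_length``.
    """
    fs = rec.sample_rate
    spw = window_length * fs
    if abs(spw - round(spw)) > 1e-9:
        raise ValueError(
            f"window_length {window_length}s is not an integer number of samples at {fs} Hz"
        )
    spw = int(round(spw))
    if rec.n_samples % spw != 0:
        raise ValueError(
            f"duration {rec.duration:.3f}s is not a multiple of the {window_length}s "
            "window; segment the recording first"
        )
    n_win = rec.n_samples // spw
    out = np.empty((rec.n_channels, n_win, len(CANONICAL_BANDS)))
    for b, band in enumerate(CANONICAL_BANDS):
        sos = band_sos(band.low, band.high, fs)
        filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
        out[:, :, b] = _window_de(filtered, spw)
    return DETensor(values=out, window_length=window_length)


def _kalman_rts(y: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Fixed-interval smoother for scalar random-walk states, vectorized
    over the leading axis. y: (M, T); q, r: (M,)."""
    m, t = y.shape
    xf = np.empty_like(y)
    pf = np.empty_like(y)
    x = y[:, 0].copy()
    p = r.copy()
    xf[:, 0] = x
    pf[:, 0] = p
    for k in range(1, t):
        p_pred = p + q
        gain = p_pred / (p_pred + r)
        x = x + gain * (y[:, k] - x)
        p = (1.0 - gain) * p_pred
        xf[:, k] = x
        pf[:, k] = p
    xs = np.empty_like(y)
    xs[:, -1] = xf[:, -1]
    for k in range(t - 2, -1, -1):
        p_pred = pf[:, k] + q
        c = pf[:, k] / p_pred
        xs[:, k] = xf[:, k] + c * (xs[:, k + 1] - xf[:, k])
    return xs


def _smooth_rows(y: np.ndarray, config: LDSConfig) -> np.ndarray:
    """Smooth each row of a (M, T) array independently."""
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    m, t = y.shape
    if t <= 1:
        return y.copy()
    if config.method == "moving_average":
        size = max(1, int(round(config.window)))
        return ndimage.uniform_filter1d(y, size=size, axis=1, mode="nearest")
    diff_var = np.var(np.diff(y, axis=1), axis=1)
    if config.obs_noise == "auto":
        r = 0.5 * diff_var
    else:
        r = np.full(m, float(config.obs_noise))
    if config.state_noise == "auto":
        q = r / (config.window ** 2)
    else:
        q = np.full(m, float(config.state_noise))
    flat = r <= 0
    r = np.where(flat, 1.0, r)
    q = np.where(q <= 0, r * 1e-12, q)
    out = _kalman_rts(y, q, r)
    # rows with no fluctuation are fixed points by contract
    out[flat] = y[flat]
    return out


def lds_smooth(series: np.ndarray, config: LDSConfig | None = None) -> np.ndarray:
    """Smooth a single per-window feature sequence; length is preserved."""
    config = config or LDSConfig()
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("lds_smooth expects a 1-D series; use smooth_tensor for tensors")
    if y.size == 0:
        raise ValueError("series must be non-empty")
    return _smooth_rows(y[None, :], config)[0]


def smooth_tensor(tensor: DETensor, config: LDSConfig | None = None) -> DETensor:
    """Apply the smoother independently per (channel, band) sequence."""
    config = config or LDSConfig()
    c, t, b = tensor.shape
    rows = tensor.values.transpose(0, 2, 1).reshape(c * b, t)
    smoothed = _smooth_rows(rows, config)
    values = smoothed.reshape(c, b, t).transpose(0, 2, 1)
    return DETensor(values=values, window_length=tensor.window_length, bands=tensor.bands)


def minmax_standardize(seq: np.ndarray) -> np.ndarray:
    """Map a sequence affinely onto [0, 1]: min -> 0, max -> 1.

    A degenerate (constant) input maps to all 0.5 with a warning.
    """
    x = np.asarray(seq, dtype=float)
    if x.size == 0:
        raise ValueError("sequence must be non-empty")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("min-max standardization of a constant sequence; returning 0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def tensor_to_plane(tensor: DETensor) -> np.ndarray:
    """Documented 2-D layout: bands stacked vertically over channels.

    Row ``b * n_channels + c`` holds channel ``c`` of band ``b``; columns are
    the time windows. A conformant tensor yields a 310 x 180 plane.
    """
    c, t, b = tensor.shape
    return tensor.values.transpose(2, 0, 1).reshape(b * c, t)


def to_feature_image(tensor: DETensor) -> FeatureImage:
    """Resample the layout plane to 224 x 224 and min-max standardize it."""
    if not tensor.is_pipeline_conformant():
        raise ValueError(
            f"feature imaging requires a {N_CHANNELS} x {CONFORMANT_WINDOWS} x "
            f"{len(CANONICAL_BANDS)} tensor, got {tensor.shape}"
        )
    plane = tensor_to_plane(tensor)
    zoom = (IMAGE_SHAPE[0] / plane.shape[0], IMAGE_SHAPE[1] / plane.shape[1])
    resampled = ndimage.zoom(plane, zoom, order=1, mode="nearest", grid_mode=True)
    lo, hi = float(resampled.min()), float(resampled.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        values = np.full(IMAGE_SHAPE, 0.5)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = minmax_standardize(resampled)
    return FeatureImage(values=values, scale_min=lo, scale_max=hi)


def featurize_recording(rec, window_length: float = 1.0,
                        lds: LDSConfig | None = None) -> FeatureImage:
    """Full chain recording -> DE tensor -> LDS smoothing -> feature image."""
    tensor = extract_de_tensor(rec, window_length=window_length)
    tensor = smooth_tensor(tensor, lds)
    return to_feature_image(tensor)
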