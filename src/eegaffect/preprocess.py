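"""Standardize raw recordings: 200 Hz rate, 0-75 Hz passband, fixed-length segments.

The "0-75 Hz bandpass" contract is realized as a zero-phase Butterworth
lowpass at 75 Hz (DC retained); a nonzero lower edge selects a true
bandpass. Filters are applied forward-backward (``sosfiltfilt``) so windowed
features see no group delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import RawRecording

__all__ = ["PreprocessConfig", "resample", "bandpass", "segment", "preprocess"]

#: IIR order used for the passband filter (applied forward-backward).
FILTER_ORDER = 5


@dataclass
class PreprocessConfig:
    target_rate: float = 200.0
    band_low: float = 0.0
    band_high: float = 75.0
    segment_length: float = 180.0
    filter_order: int = FILTER_ORDER

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be > 0")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")
        if not (0 <= self.band_low < self.band_high):
            raise ValueError("need 0 <= band_low < band_high")


def resample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Polyphase resampling to ``target_rate`` with built-in anti-aliasing.

    Equal input and output rates return an identical copy.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be > 0, got {target_rate}")
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    if target_rate == rec.sample_rate:
        return rec.with_data(rec.data.copy())
    ratio = Fraction(int(round(target_rate * 1000)), int(round(rec.sample_rate * 1000)))
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return rec.with_data(out, sample_rate=target_rate)


def bandpass(rec: RawRecording, low: float = 0.0, high: float = 75.0,
             order: int = FILTER_ORDER) -> RawRecording:
    """Zero-phase passband filter; ``low == 0`` degrades to a pure lowpass."""
    nyq = rec.sample_rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"upper edge {high} Hz must be below Nyquist ({nyq} Hz at "
            f"{rec.sample_rate} Hz)"
        )
    if low < 0 or low >= high:
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if low == 0:
        sos = signal.butter(order, high, btype="lowpass", fs=rec.sample_rate, output="sos")
    else:
        sos = signal.butter(order, [low, high], btype="bandpass",
                            fs=rec.sample_rate, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def segment(rec: RawRecording, length: float) -> RawRecording:
    """Keep the first ``length`` seconds of every channel."""
    if length <= 0:
        raise ValueError("length must be > 0")
    n = int(round(length * rec.sample_rate))
    if rec.n_samples < n:
        deficit = (n - rec.n_samples) / rec.sample_rate
        raise ValueError(
            f"recording is {deficit:.3f}s too short for a {length}s segment "
            f"(have {rec.duration:.3f}s)"
        )
    return rec.with_data(rec.data[:, :n].copy())


def preprocess(rec: RawRecording, config: PreprocessConfig | None = None) -> RawRecording:
    """resample -> bandpass -> segment with the standard defaults."""
    config = config or PreprocessConfig()
    rec = resample(rec, config.target_rate)
    rec = bandpass(rec, config.band_low, config.band_high, config.filter_order)
    return segment(rec, config.segment_length)
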