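"""Session-level scoring: classify a measurement window and map it to 1-100.

A session spans 60 s in total; EEG is acquired during the first 30 s at
200 Hz (one sample every 5 ms) and the remainder is analysis/visualization
time. Acquisition windows shorter than the 180-window training tensors are
bridged by linearly resampling the window axis to length 180 before
imaging.

The pleasure score is ``clamp(round(100 * (p_pos + 0.5 * p_neu)), 1, 100)``:
the simplest mapping that is monotone in the positive-class probability and
sends certain-neutral to mid-scale (100 / 50 / 1 for the pure classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

import numpy as np
from scipy import ndimage

from . import features, preprocess
from .core import N_CHANNELS, RawRecording
from .model.network import ResidualClassifier

__all__ = ["SessionConfig", "SessionResult", "classify_session",
           "pleasure_score", "improvement", "run_session"]

_CONTEXTS = ("baseline", "stimulus")


@dataclass
class SessionConfig:
    total_duration: float = 60.0
    acquisition_duration: float = 30.0
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not (0 < self.acquisition_duration <= self.total_duration):
            raise ValueError("need 0 < acquisition_duration <= total_duration")

    @property
    def sample_interval_ms(self) -> float:
        """Inter-sample interval in milliseconds (5 ms at 200 Hz)."""
        return 1000.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        """Samples consumed per channel during acquisition."""
        return int(round(self.acquisition_duration * self.sample_rate))


@dataclass
class SessionResult:
    probabilities: np.ndarray
    pleasure_score: int
    context: str
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        _validate_probabilities(self.probabilities)
        if not (1 <= self.pleasure_score <= 100):
            raise ValueError("pleasure_score must lie in [1, 100]")
        if self.context not in _CONTEXTS:
            raise ValueError(f"context must be one of {_CONTEXTS}")


def _validate_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-class probability vector, got shape {p.shape}")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    return p


def classify_session(rec: RawRecording, model: ResidualClassifier,
                     config: SessionConfig | None = None) -> np.ndarray:
    """Run preprocess -> features -> classifier on one acquisition window.

    Returns the softmax probability vector over (negative, neutral,
    positive). Deterministic given (recording, model).
    """
    config = config or SessionConfig()
    if rec.n_channels != N_CHANNELS:
        raise ValueError(
            f"session recordings must use the {N_CHANNELS}-channel 10-20 layout, "
            f"got {rec.n_channels} channels"
        )
    rec = preprocess.resample(rec, config.sample_rate)
    if config.sample_rate / 2.0 > 75.0:
        rec = preprocess.bandpass(rec, 0.0, 75.0)
    rec = preprocess.segment(rec, config.acquisition_duration)
    tensor = features.extract_de_tensor(rec, window_length=1.0)
    tensor = features.smooth_tensor(tensor)
    n_win = tensor.shape[1]
    if n_win != features.CONFORMANT_WINDOWS:
        zoom = (1.0, features.CONFORMANT_WINDOWS / n_win, 1.0)
        values = ndimage.zoom(tensor.values, zoom, order=1, mode="nearest", grid_mode=True)
        tensor = features.DETensor(values=values, window_length=tensor.window_length,
                                   bands=tensor.bands)
    image = features.to_feature_image(tensor)
    return model.predict_proba(image.values[None])[0]


def pleasure_score(p: np.ndarray) -> int:
    """Map class probabilities to the 1-100 pleasure scale."""
    p = _validate_probabilities(p)
    raw = 100.0 * (p[2] + 0.5 * p[1])
    return int(np.clip(np.floor(raw + 0.5), 1, 100))


def improvement(baseline: SessionResult, stimulus: SessionResult) -> float:
    """Signed stimulus-minus-baseline pleasure delta."""
    return float(stimulus.pleasure_score - baseline.pleasure_score)


def run_session(rec: RawRecording, model: ResidualClassifier, context: str,
                config: SessionConfig | None = None) -> SessionResult:
    """Classify a session and package the scored result."""
    probs = classify_session(rec, model, config)
    return SessionResult(probabilities=probs, pleasure_score=pleasure_score(probs),
                         context=context)
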