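"""Shared domain types for the EEG affect pipeline.

Holds the canonical frequency bands, the class-conditional variance
profiles used by the synthetic generator, and the raw recording container
that every stage of the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "BAND_NAMES",
    "ClassProfile",
    "RawRecording",
    "EMOTION_LABELS",
    "LABEL_TO_INDEX",
    "INDEX_TO_LABEL",
    "CLASS_NAMES",
    "N_CHANNELS",
]

#: Number of scalp channels every pipeline-conformant recording carries.
N_CHANNELS = 62

#: Valid emotion labels: negative, neutral, positive.
EMOTION_LABELS = (-1, 0, 1)

#: Fixed label -> class-index mapping used by the classifier head.
LABEL_TO_INDEX = {-1: 0, 0: 1, 1: 2}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}
CLASS_NAMES = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )


#: The five canonical EEG bands, in fixed order.
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)

BAND_NAMES = tuple(b.name for b in CANONICAL_BANDS)


@dataclass(frozen=True)
class ClassProfile:
    """Per-band signal variance profile for one emotion class.

    ``band_variance`` is ordered like :data:`CANONICAL_BANDS` and holds the
    target signal variance (uV^2) of each band-limited component.
    """

    label: int
    band_variance: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in EMOTION_LABELS:
            raise ValueError(f"label must be one of {EMOTION_LABELS}, got {self.label}")
        bv = tuple(float(v) for v in self.band_variance)
        if len(bv) != len(CANONICAL_BANDS):
            raise ValueError(
                f"band_variance needs {len(CANONICAL_BANDS)} entries, got {len(bv)}"
            )
        if any(v <= 0 for v in bv):
            raise ValueError("all band variances must be > 0")
        object.__setattr__(self, "band_variance", bv)

    def variance_array(self) -> np.ndarray:
        return np.asarray(self.band_variance, dtype=float)


@dataclass
class RawRecording:
    """A channels x samples EEG matrix (uV) with its sampling rate.

    ``label`` is the optional emotion label in {-1, 0, +1}.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: Sequence[str] = field(default_factory=list)
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_names:
            self.channel_names = list(self.channel_names)
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for "
                    f"{self.data.shape[0]} data rows"
                )
        if self.label is not None and self.label not in EMOTION_LABELS:
            raise ValueError(f"label must be in {EMOTION_LABELS}, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def is_pipeline_conformant(self) -> bool:
        return self.n_channels == N_CHANNELS

    def with_data(self, data: np.ndarray, sample_rate: Optional[float] = None) -> "RawRecording":
        """Copy of this recording with new samples (metadata preserved)."""
        return replace(
            self,
            data=data,
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
        )
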