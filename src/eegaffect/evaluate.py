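"""Detector-vs-questionnaire evaluation arithmetic.

Accuracy is read as ``100 - mean absolute error`` on the shared 1-100
pleasure scale (a mean error of 2.77 reports as 97.23, i.e. ~97%). Errors
are absolute differences; group contrasts are first-minus-second
differences of group means compared across the detector and questionnaire
sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["EvaluationReport", "ContrastResult", "pairwise_error",
           "contrast_consistency", "questionnaire_mean"]


@dataclass(frozen=True)
class EvaluationReport:
    per_pair_errors: tuple[float, ...]
    mean_error: float
    accuracy_percent: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.mean_error < 0:
            raise ValueError("mean_error must be >= 0")
        if abs(self.accuracy_percent - (100.0 - self.mean_error)) > 1e-9:
            raise ValueError("accuracy_percent must equal 100 - mean_error")


@dataclass(frozen=True)
class ContrastResult:
    detector_contrast: float
    reference_contrast: float
    discrepancy: float

    def __post_init__(self) -> None:
        if self.discrepancy < 0:
            raise ValueError("discrepancy must be >= 0")


def _check_scores(scores: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.any(arr < 1) or np.any(arr > 100):
        raise ValueError(f"{name} must lie in [1, 100]")
    return arr


def pairwise_error(detector_scores: Sequence[float],
                   reference_scores: Sequence[float]) -> EvaluationReport:
    """Per-pair absolute errors, their mean, and the derived accuracy."""
    det = _check_scores(detector_scores, "detector_scores")
    ref = _check_scores(reference_scores, "reference_scores")
    if det.shape != ref.shape:
        raise ValueError(
            f"score lists differ in length: {det.size} vs {ref.size}"
        )
    errors = np.abs(det - ref)
    mean_error = float(errors.mean())
    return EvaluationReport(
        per_pair_errors=tuple(float(e) for e in errors),
        mean_error=mean_error,
        accuracy_percent=100.0 - mean_error,
        n_pairs=int(det.size),
    )


def contrast_consistency(detector_group_means: tuple[float, float],
                         reference_group_means: tuple[float, float]) -> ContrastResult:
    """First-minus-second group-mean contrasts and their absolute discrepancy."""
    d1, d2 = (float(v) for v in detector_group_means)
    r1, r2 = (float(v) for v in reference_group_means)
    detector_contrast = d1 - d2
    reference_contrast = r1 - r2
    return ContrastResult(
        detector_contrast=detector_contrast,
        reference_contrast=reference_contrast,
        discrepancy=abs(detector_contrast - reference_contrast),
    )


def questionnaire_mean(scores: Sequence[float]) -> float:
    """Arithmetic mean of 1-100 questionnaire ratings."""
    return float(_check_scores(scores, "scores").mean())
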