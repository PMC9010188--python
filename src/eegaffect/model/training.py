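"""Training loop: Adam, batch-5 epochs, seeded 9:1 split, best-epoch selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..core import LABEL_TO_INDEX
from .layers import categorical_crossentropy, softmax
from .network import ResidualClassifier

__all__ = ["TrainingConfig", "EpochRecord", "Adam", "split_dataset", "one_hot",
           "train", "select_best_epoch", "evaluate_accuracy"]


@dataclass
class TrainingConfig:
    optimizer: str = "adam"
    batch_size: int = 5
    epochs: int = 50
    seed: int = 0
    split_ratio: tuple[int, int] = (9, 1)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    keep_checkpoints: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int  # 1-based
    test_accuracy: float
    train_loss: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.test_accuracy <= 1.0):
            raise ValueError("test_accuracy must lie in [0, 1]")


class Adam:
    """Adam at its conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (_, p, g) in enumerate(params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def split_dataset(n: int, ratio: tuple[int, int] = (9, 1), seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition.

    The test size is round-half-up of ``n * test_share`` — the only rounding
    rule consistent with 675 -> 607 train / 68 test at 9:1.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    total = sum(ratio)
    n_test = int(np.floor(n * ratio[1] / total + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate split: n={n} at ratio {ratio[0]}:{ratio[1]}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def one_hot(labels: Sequence[int], n_classes: int = 3) -> np.ndarray:
    """Map emotion labels in {-1, 0, +1} to one-hot rows (indices 0/1/2)."""
    idx = np.array([LABEL_TO_INDEX[int(l)] for l in labels])
    out = np.zeros((len(idx), n_classes), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def evaluate_accuracy(classifier: ResidualClassifier, images: np.ndarray,
                      labels: Sequence[int]) -> float:
    probs = classifier.predict_proba(images)
    pred = probs.argmax(axis=1)
    truth = np.array([LABEL_TO_INDEX[int(l)] for l in labels])
    return float((pred == truth).mean())


def train(classifier: ResidualClassifier,
          train_images: np.ndarray, train_labels: Sequence[int],
          test_images: np.ndarray, test_labels: Sequence[int],
          config: TrainingConfig | None = None,
          ) -> tuple[list[EpochRecord], list[dict[str, np.ndarray]]]:
    """Run the full training protocol; returns per-epoch records + checkpoints.

    Each epoch shuffles the training set (seeded), steps Adam on batches of
    ``batch_size`` (last batch may be smaller) against the mean categorical
    cross-entropy, then measures accuracy on the held-out test set. The whole
    run is reproducible from ``config.seed``.
    """
    config = config or TrainingConfig()
    train_images = np.asarray(train_images, dtype=np.float32)
    test_images = np.asarray(test_images, dtype=np.float32)
    if len(train_images) == 0 or len(test_images) == 0:
        raise ValueError("train and test sets must be non-empty")
    if len(train_images) != len(train_labels) or len(test_images) != len(test_labels):
        raise ValueError("images and labels must have equal length")
    y_train = one_hot(train_labels, classifier.config.n_classes)
    rng = np.random.default_rng(config.seed)
    opt = Adam(classifier.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    records: list[EpochRecord] = []
    checkpoints: list[dict[str, np.ndarray]] = []
    n = len(train_images)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = train_images[idx], y_train[idx]
            logits = classifier.forward_logits(xb, train=True)
            probs = softmax(logits, axis=1)
            losses.append(categorical_crossentropy(yb, probs))
            classifier.backward((probs - yb) / len(idx))
            opt.step(classifier.parameters())
        acc = evaluate_accuracy(classifier, test_images, test_labels)
        records.append(EpochRecord(epoch=epoch, test_accuracy=acc,
                                   train_loss=float(np.mean(losses))))
        if config.keep_checkpoints:
            checkpoints.append(classifier.state_dict())
    return records, checkpoints


def select_best_epoch(records: Sequence[EpochRecord]) -> int:
    """Earliest epoch attaining the maximum test accuracy (1-based)."""
    if not records:
        raise ValueError("no epoch records to select from")
    best = max(r.test_accuracy for r in records)
    for r in records:
        if r.test_accuracy == best:
            return r.epoch
    raise AssertionError("unreachable")
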