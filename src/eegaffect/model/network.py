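"""Residual CNN classifier: bottleneck blocks, GAP head, 3-way softmax.

Two presets are provided. ``resnet50`` mirrors the canonical 50-layer
architecture (stage block counts [3, 4, 6, 3], 16 bottleneck blocks, one
stem convolution and one final dense layer = 50 weighted layers).
``small`` is a desk-scale variant with the same topology at [1, 1, 1, 1]
blocks and narrow channels, trainable on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm2d, Conv2d, Dense, GlobalAvgPool, Layer,
                     MaxPool2d, ReLU, Sequential, softmax)

__all__ = ["ResidualBlockConfig", "NetworkConfig", "Bottleneck",
           "ResidualClassifier", "build_network"]


@dataclass(frozen=True)
class ResidualBlockConfig:
    """Shape contract of one residual block."""

    kind: str  # "build" (2-layer) or "bottleneck" (3-layer)
    channels_in: int
    channels_out: int
    stride: int = 1
    projection: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("build", "bottleneck"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        needs_projection = self.channels_in != self.channels_out or self.stride != 1
        if needs_projection and not self.projection:
            raise ValueError(
                "projection shortcut required when channels or resolution change"
            )


@dataclass
class NetworkConfig:
    depth_preset: str = "resnet50"
    stage_block_counts: tuple[int, ...] = (3, 4, 6, 3)
    stage_widths: tuple[tuple[int, int], ...] = (
        (64, 256), (128, 512), (256, 1024), (512, 2048))
    stem_channels: int = 64
    stem_stride: int = 2
    input_shape: tuple[int, int] = (224, 224)
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.stage_block_counts) != len(self.stage_widths):
            raise ValueError("stage_block_counts and stage_widths must align")
        if self.depth_preset == "resnet50":
            if tuple(self.stage_block_counts) != (3, 4, 6, 3):
                raise ValueError("resnet50 preset requires stage counts (3, 4, 6, 3)")
            if self.input_shape != (224, 224):
                raise ValueError("resnet50 preset requires 224 x 224 input")

    @classmethod
    def resnet50(cls) -> "NetworkConfig":
        return cls()

    @classmethod
    def small(cls) -> "NetworkConfig":
        """Narrow [1,1,1,1] variant for CPU-scale training and tests."""
        return cls(
            depth_preset="small",
            stage_block_counts=(1, 1, 1, 1),
            stage_widths=((4, 16), (8, 32), (16, 64), (32, 128)),
            stem_channels=8,
            stem_stride=4,
        )


class Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 residual branch plus (projected) shortcut.

    The block computes ``relu(F(x) + shortcut(x))``; the shortcut is the
    identity unless channels or resolution change, in which case a learned
    1x1 projection (with batch norm) reshapes the input.
    """

    def __init__(self, cin: int, width: int, cout: int, stride: int,
                 rng: np.random.Generator):
        self.config = ResidualBlockConfig(
            kind="bottleneck", channels_in=cin, channels_out=cout,
            stride=stride, projection=(cin != cout or stride != 1))
        self.branch = Sequential(
            Conv2d(cin, width, 1, pad=0, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, width, 3, stride=stride, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, cout, 1, pad=0, rng=rng), BatchNorm2d(cout),
        )
        if self.config.projection:
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng),
                BatchNorm2d(cout),
            )
        else:
            self.shortcut = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.branch.forward(x, train=train)
        sc = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        y = f + sc
        if train:
            self._mask = y > 0
        return np.maximum(y, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        dx = self.branch.backward(g)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(g)
        else:
            dx = dx + g
        return dx

    def parameters(self):
        out = [(f"branch.{n}", p, g) for n, p, g in self.branch.parameters()]
        if self.shortcut is not None:
            out.extend((f"shortcut.{n}", p, g) for n, p, g in self.shortcut.parameters())
        return out

    def zero_branch(self) -> None:
        """Zero every residual-branch parameter so F(x) == 0 in eval mode."""
        for _, p, _ in self.branch.parameters():
            p[...] = 0

    @property
    def n_weighted_layers(self) -> int:
        # three branch convolutions; projection shortcuts are not counted
        return 3


class ResidualClassifier:
    """Stem conv -> four residual stages -> GAP -> dense softmax head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem = Sequential(
            Conv2d(1, config.stem_channels, 7, stride=config.stem_stride, rng=rng),
            BatchNorm2d(config.stem_channels), ReLU(),
        )
        self.pool = MaxPool2d(3, 2, 1)
        self.blocks: list[Bottleneck] = []
        cin = config.stem_channels
        for stage, (count, (width, cout)) in enumerate(
                zip(config.stage_block_counts, config.stage_widths)):
            for b in range(count):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(Bottleneck(cin, width, cout, stride, rng))
                cin = cout
        self.gap = GlobalAvgPool()
        self.head = Dense(cin, config.n_classes, rng=rng)

    # -- introspection -----------------------------------------------------
    @property
    def n_residual_blocks(self) -> int:
        return len(self.blocks)

    def count_weighted_layers(self) -> int:
        """Stem convolution + branch convolutions + final dense layer."""
        return 1 + sum(b.n_weighted_layers for b in self.blocks) + 1

    # -- forward / backward ------------------------------------------------
    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 224, 224) single-plane images")
        if x.shape[2:] != self.config.input_shape:
            raise ValueError(
                f"{self.config.depth_preset} preset requires "
                f"{self.config.input_shape[0]} x {self.config.input_shape[1]} input, "
                f"got {x.shape[2]} x {x.shape[3]}"
            )
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._validate_input(x)
        x = self.stem.forward(x, train=train)
        x = self.pool.forward(x, train=train)
        for block in self.blocks:
            x = block.forward(x, train=train)
        x = self.gap.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.gap.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.pool.backward(g)
        self.stem.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Softmax class probabilities over {negative, neutral, positive}."""
        x = self._validate_input(x)
        out = [softmax(self.forward_logits(x[i:i + batch_size], train=False), axis=1)
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    # -- parameter access --------------------------------------------------
    def _named_modules(self):
        yield "stem", self.stem
        for i, block in enumerate(self.blocks):
            yield f"block{i}", block
        yield "head", self.head

    def parameters(self):
        out = []
        for prefix, module in self._named_modules():
            out.extend((f"{prefix}.{n}", p, g) for n, p, g in module.parameters())
        return out

    def _named_buffers(self):
        def walk(prefix, module):
            if isinstance(module, BatchNorm2d):
                for n, s in module.state():
                    yield f"{prefix}.{n}", s
            elif isinstance(module, Sequential):
                for i, sub in enumerate(module.layers):
                    yield from walk(f"{prefix}.{i}", sub)
            elif isinstance(module, Bottleneck):
                yield from walk(f"{prefix}.branch", module.branch)
                if module.shortcut is not None:
                    yield from walk(f"{prefix}.shortcut", module.shortcut)

        for prefix, module in self._named_modules():
            yield from walk(prefix, module)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.copy() for name, p, _ in self.parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        targets = {name: p for name, p, _ in self.parameters()}
        targets.update(dict(self._named_buffers()))
        missing = set(targets) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing parameters: {sorted(missing)[:5]}")
        for name, arr in state.items():
            if name not in targets:
                raise ValueError(f"unexpected parameter {name!r} in checkpoint")
            if targets[name].shape != np.shape(arr):
                raise ValueError(f"shape mismatch for {name!r}")
            targets[name][...] = arr


def build_network(config: NetworkConfig, seed: int = 0) -> ResidualClassifier:
    """Construct a seeded classifier; initialization is a pure function of seed."""
    return ResidualClassifier(config, seed=seed)
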