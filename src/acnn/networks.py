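"""The three fixed 3D CNN architectures and their training loop.

Three volumetric classifiers operate on co-centred cubes of a candidate at
decreasing resolution: CNN-1 on 32^3 input, CNN-2 on 64^3 and CNN-3 on 96^3,
with 5, 7 and 9 layer-table rows respectively (counting the input and the
global-average-pooling rows).  Every convolution is followed by RT-ReLU — a
ReLU whose pre-activation is shifted by a fresh Gaussian offset during
training and by zero at test time.  The published layer table ends each
network at global average pooling; a single linear unit with a sigmoid maps
the pooled features to a nodule probability.

Two table cells require care.  CNN-1's first convolution is printed with
output edge 32, which is impossible for a valid 5^3 kernel on a 32^3 input
and contradicts the following pooling row (output 14 needs input 28); the
edge is 28.  CNN-3's pooling of 17 down to 9 forces ceil-mode pooling, which
is applied uniformly (even edges are unaffected).

Besides the published ``full`` profile, a ``tiny`` profile with 3^3 kernels,
a strided first convolution and ~4x narrower channels keeps the same
conv-pool alternation at roughly 1/1000 the arithmetic cost, for CPU-scale
experiments; layer-shape guarantees apply to the full profile only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _engine
from ._engine import (
    Conv3d,
    DenseHead,
    GlobalAvgPool,
    MaxPool3d,
    RandomShiftReLU,
    sigmoid,
    weighted_bce_grad,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "RtReluParams",
    "TrainConfig",
    "conv3d_out_edge",
    "pool3d_out_edge",
    "build_architecture",
    "rt_relu",
    "sample_offsets",
    "Cnn3d",
    "build_model",
    "forward",
    "train_cnn",
    "ARCH_NAMES",
]

ARCH_NAMES = ("CNN-1", "CNN-2", "CNN-3")
_ARCH_INPUT_EDGE = {"CNN-1": 32, "CNN-2": 64, "CNN-3": 96}


# ---------------------------------------------------------------------------
# Shape arithmetic
# ---------------------------------------------------------------------------

def conv3d_out_edge(in_edge: int, kernel: int, stride: int = 1, pad: int = 0) -> int:
    """Output edge of a 3D convolution: floor((n + 2p - k)/s) + 1."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if in_edge + 2 * pad < kernel:
        raise ValueError(
            f"conv kernel {kernel} does not fit input edge {in_edge} with pad {pad}"
        )
    return (in_edge + 2 * pad - kernel) // stride + 1


def pool3d_out_edge(
    in_edge: int, kernel: int = 2, stride: int = 2, ceil_mode: bool = True
) -> int:
    """Output edge of max pooling; ceil mode keeps the trailing partial window."""
    if in_edge < 1:
        raise ValueError(f"in_edge must be >= 1, got {in_edge}")
    if ceil_mode:
        return -((in_edge - kernel) // -stride) + 1
    return (in_edge - kernel) // stride + 1


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table."""

    kind: str  # input | conv3d | maxpool3d | global_avg_pool
    in_shape: tuple[int, ...]  # (channels, d, h, w)
    out_shape: tuple[int, ...]
    kernel: int | None = None
    stride: int | None = None
    pad: int = 0


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_edge: int
    layers: tuple[LayerSpec, ...]
    profile: str = "full"

    @property
    def n_rows(self) -> int:
        return len(self.layers)

    def conv_channels(self) -> list[int]:
        return [l.out_shape[0] for l in self.layers if l.kind == "conv3d"]

    def spatial_trace(self) -> list[int]:
        """Output edge after every conv/pool layer, in order."""
        return [
            l.out_shape[1] for l in self.layers if l.kind in ("conv3d", "maxpool3d")
        ]

    def to_manifest(self) -> dict:
        return {
            "name": self.name,
            "input_edge": self.input_edge,
            "profile": self.profile,
            "layers": [
                {
                    "kind": l.kind,
                    "in_shape": list(l.in_shape),
                    "out_shape": list(l.out_shape),
                    "kernel": l.kernel,
                    "stride": l.stride,
                    "pad": l.pad,
                }
                for l in self.layers
            ],
        }


# (channels, kernel, stride) per conv; "P" marks a 2x2x2 ceil-mode pool.
_FULL_PLANS: dict[str, list] = {
    "CNN-1": [(20, 5, 1), "P", (50, 5, 1)],
    "CNN-2": [(20, 5, 1), "P", (50, 5, 1), "P", (100, 4, 1)],
    "CNN-3": [(20, 5, 1), "P", (50, 5, 1), "P", (100, 5, 1), "P", (100, 5, 1)],
}
_TINY_PLANS: dict[str, list] = {
    "CNN-1": [(5, 3, 1), "P", (12, 3, 1)],
    "CNN-2": [(5, 3, 2), "P", (12, 3, 1), "P", (25, 3, 1)],
    "CNN-3": [(5, 3, 3), "P", (12, 3, 1), "P", (25, 3, 1), "P", (25, 3, 1)],
}


def build_architecture(name: str, profile: str = "full") -> ArchitectureSpec:
    """Construct the layer table of CNN-1/2/3 (5/7/9 rows in the full profile)."""
    if name not in ARCH_NAMES:
        raise ValueError(f"unknown architecture {name!r}; expected one of {ARCH_NAMES}")
    if profile not in ("full", "tiny"):
        raise ValueError(f"unknown profile {profile!r}")
    plan = (_FULL_PLANS if profile == "full" else _TINY_PLANS)[name]
    edge = _ARCH_INPUT_EDGE[name]
    layers: list[LayerSpec] = [
        LayerSpec("input", (1, edge, edge, edge), (1, edge, edge, edge))
    ]
    channels = 1
    for step in plan:
        if step == "P":
            out_edge = pool3d_out_edge(edge)
            layers.append(
                LayerSpec(
                    "maxpool3d",
                    (channels, edge, edge, edge),
                    (channels, out_edge, out_edge, out_edge),
                    kernel=2,
                    stride=2,
                )
            )
            edge = out_edge
        else:
            out_ch, kernel, stride = step
            out_edge = conv3d_out_edge(edge, kernel, stride, 0)
            layers.append(
                LayerSpec(
                    "conv3d",
                    (channels, edge, edge, edge),
                    (out_ch, out_edge, out_edge, out_edge),
                    kernel=kernel,
                    stride=stride,
                )
            )
            channels, edge = out_ch, out_edge
    layers.append(
        LayerSpec("global_avg_pool", (channels, edge, edge, edge), (channels,))
    )
    spec = ArchitectureSpec(
        name=name,
        input_edge=_ARCH_INPUT_EDGE[name],
        layers=tuple(layers),
        profile=profile,
    )
    if profile == "full":
        expected_rows = {"CNN-1": 5, "CNN-2": 7, "CNN-3": 9}[name]
        assert spec.n_rows == expected_rows
    return spec


# ---------------------------------------------------------------------------
# RT-ReLU functional interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RtReluParams:
    """Std. dev. of the Gaussian pre-activation offsets and train/test mode."""

    sigma: float = 0.05
    mode: str = "train"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.mode not in ("train", "test"):
            raise ValueError(f"mode must be 'train' or 'test', got {self.mode!r}")


def rt_relu(
    x: np.ndarray, offsets: np.ndarray | None = None, mode: str = "test"
) -> np.ndarray:
    """y_i = x_i + a_i if x_i + a_i > 0 else 0; test mode uses a_i = 0 (plain ReLU)."""
    x = np.asarray(x)
    if mode == "test" or offsets is None:
        pre = x
    else:
        offsets = np.asarray(offsets)
        if offsets.shape != x.shape:
            raise ValueError(
                f"offsets shape {offsets.shape} does not match input {x.shape}"
            )
        pre = x + offsets
    return np.where(pre > 0, pre, 0)


def sample_offsets(
    shape: tuple[int, ...], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Fresh i.i.d. N(0, sigma^2) offsets; sigma = 0 gives exact zeros."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma, size=shape)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """SGD hyperparameters: lr 0.001, weight decay 0.0005, 30 epochs by default."""

    learning_rate: float = 0.001
    weight_decay: float = 0.0005
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    rt_relu_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class Cnn3d:
    """A concrete network assembled from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, sigma: float = 0.05):
        self.spec = spec
        self.sigma = sigma
        rng = np.random.default_rng(seed)
        self.layers: list = []
        gap_channels = None
        for l in spec.layers:
            if l.kind == "input":
                continue
            if l.kind == "conv3d":
                self.layers.append(
                    Conv3d(l.in_shape[0], l.out_shape[0], l.kernel, l.stride, rng)
                )
                self.layers.append(RandomShiftReLU(sigma))
            elif l.kind == "maxpool3d":
                self.layers.append(MaxPool3d())
            elif l.kind == "global_avg_pool":
                self.layers.append(GlobalAvgPool())
                gap_channels = l.in_shape[0]
        self.head = DenseHead(gap_channels, rng)

    # -- inference ---------------------------------------------------------

    def forward_logits(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        h = np.asarray(x, dtype=_engine.DTYPE)
        for layer in self.layers:
            if isinstance(layer, RandomShiftReLU):
                h = layer.forward(h, train, rng)
            else:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Test-mode (zero-offset, deterministic) nodule probabilities."""
        x = np.asarray(x, dtype=_engine.DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.ndim == 4:
            x = x[:, None]
        probs = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            stop = min(start + batch_size, x.shape[0])
            probs[start:stop] = sigmoid(self.forward_logits(x[start:stop]))
        return probs

    def shape_trace(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Per-layer output shapes of an actual forward pass (sans batch axis)."""
        h = np.asarray(x, dtype=_engine.DTYPE)
        if h.ndim == 3:
            h = h[None, None]
        trace = []
        for layer in self.layers:
            if isinstance(layer, RandomShiftReLU):
                h = layer.forward(h, False, None)
                continue  # activation preserves shape; not a table row
            h = layer.forward(h, False)
            trace.append(tuple(h.shape[1:]))
        return trace

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def sgd_step(self, lr: float, weight_decay: float) -> None:
        for layer in [*self.layers, self.head]:
            for param, grad in layer.parameters():
                param -= lr * (grad + weight_decay * param)

    # -- persistence -------------------------------------------------------

    def save(self, weights_path: str | Path, manifest_path: str | Path | None = None):
        weights_path = Path(weights_path)
        arrays = {}
        for i, layer in enumerate([*self.layers, self.head]):
            for j, (param, _) in enumerate(layer.parameters()):
                arrays[f"layer{i}_param{j}"] = param
        np.savez(weights_path, **arrays)
        if manifest_path is not None:
            manifest = self.spec.to_manifest()
            manifest["sigma"] = self.sigma
            Path(manifest_path).write_text(json.dumps(manifest, indent=2))
        return weights_path

    @classmethod
    def load(cls, weights_path: str | Path, manifest_path: str | Path) -> "Cnn3d":
        manifest = json.loads(Path(manifest_path).read_text())
        spec = build_architecture(manifest["name"], manifest["profile"])
        model = cls(spec, seed=0, sigma=manifest.get("sigma", 0.05))
        with np.load(weights_path) as data:
            for i, layer in enumerate([*model.layers, model.head]):
                for j, (param, _) in enumerate(layer.parameters()):
                    param[...] = data[f"layer{i}_param{j}"]
        return model


def build_model(name: str, profile: str = "full", seed: int = 0, sigma: float = 0.05) -> Cnn3d:
    return Cnn3d(build_architecture(name, profile), seed=seed, sigma=sigma)


def forward(model: Cnn3d, cube: np.ndarray) -> float:
    """Test-mode nodule probability for one cube matching the model's input edge."""
    cube = np.asarray(cube)
    edge = model.spec.input_edge
    if cube.shape != (edge, edge, edge):
        raise ValueError(
            f"{model.spec.name} expects a {edge}^3 cube, got shape {cube.shape}"
        )
    return float(model.predict_proba(cube)[0])


def train_cnn(
    model: Cnn3d,
    patches: np.ndarray,
    labels: Sequence[int],
    sample_weights: Sequence[float],
    config: TrainConfig,
) -> tuple[Cnn3d, np.ndarray]:
    """Weighted-cross-entropy SGD training; returns test-mode train-set probabilities.

    ``labels`` use the {-1, +1} coding; each sample's loss term is multiplied
    by its (normalized, non-negative) weight, so the boosting distribution
    enters the optimisation directly rather than through resampling.
    Minibatch gradients are scaled by m/|B| so uniform weights 1/m reduce to
    the ordinary batch-mean gradient.
    """
    x = np.asarray(patches, dtype=_engine.DTYPE)
    if x.ndim == 4:
        x = x[:, None]
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")
    w = np.asarray(sample_weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("sample weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"sample weights must sum to 1, got {w.sum()}")
    if len({int(v) for v in labels}) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    m = x.shape[0]
    targets = (labels > 0).astype(np.float64)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.epochs):
        order = rng.permutation(m)
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(x[idx], train=True, rng=rng)
            scale = m / len(idx)
            _, grad = weighted_bce_grad(logits, targets[idx], w[idx] * scale)
            model.backward(grad)
            model.sgd_step(config.learning_rate, config.weight_decay)
    return model, model.predict_proba(x, batch_size=config.batch_size)
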