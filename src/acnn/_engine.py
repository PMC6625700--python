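"""Minimal 3D convolutional network engine on NumPy.

The classifiers used here are three small *fixed* volumetric architectures,
so a full autodiff framework is unnecessary: each layer implements an
explicit forward and backward pass, convolution is lowered to a matrix
product (im2col / col2im), and optimisation is plain stochastic gradient
descent with L2 weight decay.  All tensors are ``float32``; batch layout is
``(N, C, D, H, W)``.

Layers
------
``Conv3d``            valid (zero-pad-free) cross-correlation, stride >= 1
``MaxPool3d``         2x2x2, stride 2, ceil mode (a trailing partial window
                      is pooled rather than dropped)
``RandomShiftReLU``   ReLU whose pre-activation is shifted by i.i.d.
                      Gaussian offsets during training and by zero at test
                      time (RT-ReLU)
``GlobalAvgPool``     per-channel spatial mean
``DenseHead``         single linear unit producing the nodule logit
"""

from __future__ import annotations

from itertools import product
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv3d:
    """Valid 3D convolution (cross-correlation) via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        if stride < 1:
            raise ValueError("stride must be >= 1")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel, kernel)
        ).astype(DTYPE)
        self.bias = np.zeros(out_channels, dtype=DTYPE)
        self.kernel = kernel
        self.stride = stride
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, d, h, w = in_shape
        k, s = self.kernel, self.stride
        if min(d, h, w) < k:
            raise ValueError(
                f"conv kernel {k} larger than input spatial extent {(d, h, w)}"
            )
        return (
            self.weight.shape[0],
            (d - k) // s + 1,
            (h - k) // s + 1,
            (w - k) // s + 1,
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n = x.shape[0]
        k, s = self.kernel, self.stride
        co, ci = self.weight.shape[:2]
        windows = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        windows = windows[:, :, ::s, ::s, ::s]
        dp, hp, wp = windows.shape[2:5]
        cols = np.ascontiguousarray(
            windows.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        ).reshape(n * dp * hp * wp, ci * k**3)
        wmat = self.weight.reshape(co, ci * k**3)
        out = cols @ wmat.T + self.bias
        out = out.reshape(n, dp, hp, wp, co).transpose(0, 4, 1, 2, 3)
        if train:
            self._cache = (x.shape, cols, (dp, hp, wp))
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward(train=True)"
        x_shape, cols, (dp, hp, wp) = self._cache
        n = x_shape[0]
        k, s = self.kernel, self.stride
        co, ci = self.weight.shape[:2]
        gyc = np.ascontiguousarray(
            grad_out.transpose(0, 2, 3, 4, 1)
        ).reshape(n * dp * hp * wp, co)
        wmat = self.weight.reshape(co, ci * k**3)
        self.grad_weight = (gyc.T @ cols).reshape(self.weight.shape)
        self.grad_bias = gyc.sum(axis=0)
        gcols = (gyc @ wmat).reshape(n, dp, hp, wp, ci, k, k, k)
        gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        grad_in = np.zeros(x_shape, dtype=DTYPE)
        for i, j, l in product(range(k), repeat=3):
            grad_in[
                :, :, i : i + s * dp : s, j : j + s * hp : s, l : l + s * wp : s
            ] += gcols[..., i, j, l]
        self._cache = None
        return grad_in

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        yield self.weight, self.grad_weight
        yield self.bias, self.grad_bias


class MaxPool3d:
    """2x2x2 max pooling with stride 2 in ceil mode.

    Odd spatial extents are padded with ``-inf`` so the trailing partial
    window contributes a (real-valued) maximum instead of being dropped:
    out_edge = ceil((in_edge - 2) / 2) + 1.
    """

    kernel = 2
    stride = 2

    def __init__(self) -> None:
        self._cache: tuple | None = None

    @staticmethod
    def out_edge(in_edge: int) -> int:
        return -((in_edge - 2) // -2) + 1  # ceil division

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, d, h, w = in_shape
        return (c, self.out_edge(d), self.out_edge(h), self.out_edge(w))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        do, ho, wo = self.out_edge(d), self.out_edge(h), self.out_edge(w)
        pad = ((0, 0), (0, 0), (0, 2 * do - d), (0, 2 * ho - h), (0, 2 * wo - w))
        xp = np.pad(x, pad, mode="constant", constant_values=-np.inf)
        win = xp.reshape(n, c, do, 2, ho, 2, wo, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, do, ho, wo, 8)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = ((n, c, d, h, w), (do, ho, wo), arg)
        return np.ascontiguousarray(out.astype(DTYPE))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        (n, c, d, h, w), (do, ho, wo), arg = self._cache
        flat = np.zeros((n, c, do, ho, wo, 8), dtype=DTYPE)
        np.put_along_axis(flat, arg[..., None], grad_out[..., None], axis=-1)
        gp = flat.reshape(n, c, do, ho, wo, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gp = gp.reshape(n, c, 2 * do, 2 * ho, 2 * wo)
        self._cache = None
        return np.ascontiguousarray(gp[:, :, :d, :h, :w])

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(())


class RandomShiftReLU:
    """RT-ReLU: y_i = x_i + a_i if x_i + a_i > 0 else 0.

    During training the offsets ``a_i`` are fresh i.i.d. N(0, sigma^2) draws
    per activation element per forward pass; at test time a_i = 0, which
    reduces the unit to the ordinary ReLU.
    """

    def __init__(self, sigma: float = 0.05) -> None:
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        self.sigma = sigma
        self._mask: np.ndarray | None = None

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape

    def forward(
        self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if train and self.sigma > 0:
            if rng is None:
                raise ValueError("training forward pass requires an rng")
            pre = x + rng.normal(0.0, self.sigma, size=x.shape).astype(DTYPE)
        else:
            pre = x
        mask = pre > 0
        if train:
            self._mask = mask
        return np.where(mask, pre, 0).astype(DTYPE)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        grad = grad_out * self._mask
        self._mask = None
        return grad

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(())


class GlobalAvgPool:
    """Collapse each feature channel to its spatial mean: (N,C,D,H,W)->(N,C)."""

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (in_shape[0],)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, d, h, w = self._shape
        grad = np.broadcast_to(
            grad_out[:, :, None, None, None] / (d * h * w), self._shape
        ).astype(DTYPE)
        self._shape = None
        return np.ascontiguousarray(grad)

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(())


class DenseHead:
    """Single linear unit mapping pooled features to the nodule logit."""

    def __init__(self, in_features: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.weight = rng.normal(0.0, np.sqrt(1.0 / in_features), in_features).astype(DTYPE)
        self.bias = np.zeros(1, dtype=DTYPE)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.weight + self.bias[0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x = self._cache
        self.grad_weight = grad_out @ x
        self.grad_bias = np.array([grad_out.sum()], dtype=DTYPE)
        grad_in = np.outer(grad_out, self.weight).astype(DTYPE)
        self._cache = None
        return grad_in

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        yield self.weight, self.grad_weight
        yield self.bias, self.grad_bias


def weighted_bce_grad(
    logits: np.ndarray, targets01: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy and its gradient w.r.t. the logits.

    Loss = sum_i w_i * [-(t_i log p_i + (1-t_i) log(1-p_i))] with
    p = sigmoid(logit); dL/dlogit_i = w_i (p_i - t_i).
    """
    p = sigmoid(logits)
    # log(p) = -log1p(exp(-x)); log(1-p) = -x - log1p(exp(-x))
    softplus_neg = np.logaddexp(0.0, -logits)
    loss_terms = targets01 * softplus_neg + (1.0 - targets01) * (logits + softplus_neg)
    loss = float(np.sum(weights * loss_terms))
    grad = (weights * (p - targets01)).astype(DTYPE)
    return loss, grad
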