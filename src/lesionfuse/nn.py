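"""A compact CNN engine on numpy arrays.

This module provides the layers the pipeline's backbones are assembled
from — 2-D convolution, depthwise and depthwise-separable convolution,
ReLU, max pooling, global average pooling (GAP), dense, softmax — each
with an exact analytic backward pass, plus an RMSProp optimizer and a
cross-entropy training loop.  Everything is float32/float64 numpy; there
is no implicit parallelism or hidden state, so a fixed seed yields
bit-identical training runs.

Data layout is ``(N, C, H, W)``.  Convolutions use im2col/col2im with
'same' or 'valid' padding and arbitrary stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "SeparableConv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Softmax",
    "ClassOutput",
    "Sequential",
    "RMSProp",
    "cross_entropy",
    "train_classifier",
]


# ---------------------------------------------------------------------------
# im2col plumbing


def _pad_amount(h: int, k: int, stride: int, padding: str | int) -> int:
    if isinstance(padding, int):
        return padding
    if padding == "valid":
        return 0
    if padding == "same":
        # symmetric padding so out = ceil(h / stride) for odd k
        return (k - 1) // 2
    raise ConfigurationError(f"unknown padding {padding!r}")


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold ``(N, C, H, W)`` into ``(N, C, k, k, oh, ow)`` patch views."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    if oh < 1 or ow < 1:
        raise InvalidArgumentError(
            f"spatial size {h}x{w} too small for kernel {k} stride {stride}"
        )
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ]
    return cols, (h, w)


def col2im(cols: np.ndarray, padded_hw, k: int, stride: int, pad: int):
    """Fold patch gradients back to the (unpadded) input gradient."""
    h, w = padded_hw
    n, c = cols.shape[:2]
    oh, ow = cols.shape[4:]
    dx = np.zeros((n, c, h, w), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            dx[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ] += cols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad or None, pad:-pad or None]
    return dx


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: forward/backward plus named parameter access."""

    name: str = ""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        padding: str | int = "same",
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.stride, self.padding = k, stride, padding
        self.name = name
        self._cache = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def out_channels(self) -> int:
        return self.w.shape[0]

    def forward(self, x, train=False):
        pad = _pad_amount(x.shape[2], self.k, self.stride, self.padding)
        cols, padded_hw = im2col(x, self.k, self.stride, pad)
        n, c, k, _, oh, ow = cols.shape
        flat = cols.reshape(n, c * k * k, oh * ow)
        wf = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("of,nfl->nol", wf, flat) + self.b[None, :, None]
        if train:
            self._cache = (flat, padded_hw, pad, (oh, ow), x.shape)
        return out.reshape(n, -1, oh, ow)

    def backward(self, grad):
        flat, padded_hw, pad, (oh, ow), x_shape = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, -1, oh * ow)
        wf = self.w.reshape(self.w.shape[0], -1)
        self.dw = np.einsum("nol,nfl->of", g, flat).reshape(self.w.shape)
        self.db = g.sum(axis=(0, 2))
        dflat = np.einsum("of,nol->nfl", wf, g)
        c_in = x_shape[1]
        dcols = dflat.reshape(n, c_in, self.k, self.k, oh, ow)
        return col2im(dcols, padded_hw, self.k, self.stride, pad)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class DepthwiseConv2d(Layer):
    """One k x k filter per input channel (channel multiplier 1)."""

    def __init__(
        self,
        channels: int,
        k: int = 3,
        stride: int = 1,
        padding: str | int = "same",
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((channels, k, k)) * np.sqrt(2.0 / (k * k))).astype(
            np.float32
        )
        self.b = np.zeros(channels, dtype=np.float32)
        self.k, self.stride, self.padding = k, stride, padding
        self.name = name
        self._cache = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def out_channels(self) -> int:
        return self.w.shape[0]

    def forward(self, x, train=False):
        pad = _pad_amount(x.shape[2], self.k, self.stride, self.padding)
        cols, padded_hw = im2col(x, self.k, self.stride, pad)
        out = np.einsum("cij,ncijhw->nchw", self.w, cols) + self.b[None, :, None, None]
        if train:
            self._cache = (cols, padded_hw, pad)
        return out

    def backward(self, grad):
        cols, padded_hw, pad = self._cache
        self.dw = np.einsum("nchw,ncijhw->cij", grad, cols)
        self.db = grad.sum(axis=(0, 2, 3))
        dcols = np.einsum("cij,nchw->ncijhw", self.w, grad)
        return col2im(dcols, padded_hw, self.k, self.stride, pad)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class SeparableConv2d(Layer):
    """Depthwise spatial filtering followed by a 1x1 pointwise projection."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        padding: str | int = "same",
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv2d(in_ch, k, stride, padding, rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, 1, "valid", rng)
        self.name = name

    @property
    def out_channels(self) -> int:
        return self.pointwise.out_channels

    def forward(self, x, train=False):
        return self.pointwise.forward(self.depthwise.forward(x, train), train)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))

    def params(self):
        out = {f"dw_{k}": v for k, v in self.depthwise.params().items()}
        out.update({f"pw_{k}": v for k, v in self.pointwise.params().items()})
        return out

    def grads(self):
        out = {f"dw_{k}": v for k, v in self.depthwise.grads().items()}
        out.update({f"pw_{k}": v for k, v in self.pointwise.grads().items()})
        return out


class ReLU(Layer):
    def __init__(self, name: str = ""):
        self.name = name
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int = 2, name: str = ""):
        self.k = k
        self.name = name
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        oh, ow = h // k, w // k
        xt = x[:, :, : oh * k, : ow * k].reshape(n, c, oh, k, ow, k)
        out = xt.max(axis=(3, 5))
        if train:
            self._cache = (xt, out, x.shape)
        return out

    def backward(self, grad):
        xt, out, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.k
        oh, ow = out.shape[2:]
        mask = xt == out[:, :, :, None, :, None]
        # split ties evenly so the gradient is conserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None] / counts)
        dx = np.zeros(x_shape, dtype=grad.dtype)
        dx[:, :, : oh * k, : ow * k] = g.reshape(n, c, oh * k, ow * k)
        return dx


class GlobalAvgPool(Layer):
    """Collapse each channel's spatial map to its mean: ``(N,C,H,W) -> (N,C)``."""

    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def __init__(self, name: str = ""):
        self.name = name
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)).astype(
            np.float32
        )
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.name = name
        self._x = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def in_dim(self) -> int:
        return self.w.shape[0]

    @property
    def out_dim(self) -> int:
        return self.w.shape[1]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Softmax(Layer):
    def __init__(self, name: str = "softmax"):
        self.name = name

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, grad):  # pragma: no cover - loss gradient bypasses softmax
        raise NotImplementedError("combine softmax with cross-entropy for training")


class ClassOutput(Layer):
    """Identity classification-output layer carrying the class names."""

    def __init__(self, class_names: list[str] | None = None, name: str = "classoutput"):
        self.name = name
        self.class_names = class_names

    def forward(self, x, train=False):
        return x

    def backward(self, grad):
        return grad


# ---------------------------------------------------------------------------
# model container


class Sequential:
    """An ordered stack of named layers with capture hooks for saliency."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def layer_names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    def find(self, name: str) -> int:
        for i, lay in enumerate(self.layers):
            if lay.name == name:
                return i
        raise ConfigurationError(f"layer {name!r} not found")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward in inference mode, returning every layer's output."""
        acts = []
        for lay in self.layers:
            x = lay.forward(x, train=False)
            acts.append(x)
        return acts

    def forward_to(self, x: np.ndarray, name: str) -> np.ndarray:
        stop = self.find(name)
        for lay in self.layers[: stop + 1]:
            x = lay.forward(x, train=False)
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward up to (excluding) the softmax layer."""
        for lay in self.layers:
            if isinstance(lay, Softmax):
                return x
            x = lay.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def parameters(self):
        """Yield (layer, key, array, grad-array) tuples for the optimizer."""
        for lay in self.layers:
            ps, gs = lay.params(), lay.grads()
            for key in ps:
                yield lay, key, ps[key], gs[key]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())


@dataclass
class RMSProp:
    """Root-mean-square propagation with decay ``rho`` and stability ``eps``."""

    lr: float = 1e-4
    rho: float = 0.9
    eps: float = 1e-8
    _cache: dict = field(default_factory=dict)

    def step(self, model: Sequential) -> None:
        for lay, key, p, g in model.parameters():
            ck = (id(lay), key)
            cache = self._cache.get(ck)
            if cache is None:
                cache = np.zeros_like(p)
                self._cache[ck] = cache
            cache *= self.rho
            cache += (1.0 - self.rho) * g * g
            p -= (self.lr * g / (np.sqrt(cache) + self.eps)).astype(p.dtype)


def train_classifier(
    model: Sequential,
    x: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    batch_size: int,
    optimizer: RMSProp,
    rng: np.random.Generator,
) -> list[float]:
    """Minimize cross-entropy with mini-batch RMSProp; returns per-epoch loss.

    The backward pass seeds ``(probs - onehot) / batch`` at the logits
    (the exact softmax + cross-entropy gradient) and propagates through
    every layer, so all weights — not just the new head — are updated.
    """
    n = len(labels)
    losses = []
    softmax = Softmax()
    pre_softmax = [
        lay for lay in model.layers if not isinstance(lay, (Softmax, ClassOutput))
    ]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], labels[idx]
            h = xb
            for lay in pre_softmax:
                h = lay.forward(h, train=True)
            probs = softmax.forward(h)
            epoch_loss += cross_entropy(probs, yb) * len(idx)
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            for lay in reversed(pre_softmax):
                grad = lay.backward(grad)
            optimizer.step(model)
        losses.append(epoch_loss / n)
    return losses
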