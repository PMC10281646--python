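"""Grad-CAM saliency maps over a backbone's convolutional activations.

For a target class ``c`` and a chosen convolutional layer, the class
score (pre-softmax logit) is backpropagated to that layer's activation
maps ``A_k``; the channel weights are the spatial means of those
gradients, and the class activation map is

    CAM = ReLU( sum_k w_k * A_k ),

max-normalized to [0, 1] (an identically-zero raw map stays all zero
rather than dividing by zero) and bilinearly upsampled to the input
size.  The default layer is the last convolutional layer before global
average pooling — the same activations the deep features are pooled
from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .backbones import images_to_tensor
from .errors import ConfigurationError, InvalidArgumentError
from .nn import ClassOutput, Conv2d, DepthwiseConv2d, Sequential, SeparableConv2d, Softmax

__all__ = ["CAMap", "gradcam", "overlay", "default_cam_layer"]

_CONV_TYPES = (Conv2d, DepthwiseConv2d, SeparableConv2d)


@dataclass
class CAMap:
    heat: np.ndarray
    upsampled: np.ndarray
    target_class: int
    layer: str

    def __post_init__(self):
        for m in (self.heat, self.upsampled):
            if m.min() < -1e-9 or m.max() > 1.0 + 1e-9:
                raise InvalidArgumentError("CAM values must lie in [0, 1]")

    def argmax_position(self) -> tuple[int, int]:
        """(row, col) of the hottest pixel of the upsampled map."""
        return tuple(np.unravel_index(int(np.argmax(self.upsampled)), self.upsampled.shape))


def default_cam_layer(model: Sequential) -> str:
    """Name of the last convolutional layer (the one feeding GAP)."""
    for lay in reversed(model.layers):
        if isinstance(lay, _CONV_TYPES):
            if not lay.name:
                raise ConfigurationError("last conv layer is unnamed")
            return lay.name
    raise ConfigurationError("model has no convolutional layer")


def _bilinear_resize(m: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    img = Image.fromarray(np.asarray(m, dtype=np.float32), mode="F")
    out = img.resize((hw[1], hw[0]), resample=Image.BILINEAR)
    return np.asarray(out, dtype=float)


def gradcam(
    model: Sequential,
    image: np.ndarray,
    target_class: int,
    layer: str | None = None,
) -> CAMap:
    """Class activation map of ``image`` for ``target_class``.

    ``layer`` names a convolutional layer of ``model``; by default the
    last one.  Raises :class:`ConfigurationError` for non-conv layers.
    """
    if layer is None:
        layer = default_cam_layer(model)
    idx = model.find(layer)
    if not isinstance(model.layers[idx], _CONV_TYPES):
        raise ConfigurationError(f"layer {layer!r} is not convolutional")

    x = images_to_tensor([image])
    # forward in training mode so each layer caches what backward needs
    acts = []
    h = x
    for lay in model.layers:
        if isinstance(lay, Softmax):
            break
        h = lay.forward(h, train=True)
        acts.append(h)
    logits = h
    if not 0 <= target_class < logits.shape[1]:
        raise InvalidArgumentError(f"target_class {target_class} out of range")

    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    grad = seed
    n_pre_softmax = len(acts)
    for lay in reversed(model.layers[idx + 1 : n_pre_softmax]):
        if isinstance(lay, (Softmax, ClassOutput)):
            continue
        grad = lay.backward(grad)

    A = acts[idx][0]          # (C, H', W') activations at the target layer
    dA = grad[0]              # same shape: d logit_c / d A
    weights = dA.mean(axis=(1, 2))
    raw = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)
    peak = raw.max()
    heat = raw / peak if peak > 0 else raw
    upsampled = _bilinear_resize(heat, image.shape[:2])
    upsampled = np.clip(upsampled, 0.0, 1.0)
    return CAMap(heat=heat, upsampled=upsampled, target_class=target_class, layer=layer)


def overlay(
    image: np.ndarray, cam: CAMap, colormap: str = "jet", alpha: float = 0.5
) -> np.ndarray:
    """Blend the colormapped heat map onto the image (uint8 RGB out)."""
    image = np.asarray(image)
    if cam.upsampled.shape != image.shape[:2]:
        raise InvalidArgumentError("CAM is not aligned to the image")
    cmap = colormaps[colormap]
    colored = cmap(cam.upsampled)[:, :, :3] * 255.0
    blended = (1.0 - alpha) * image.astype(float) + alpha * colored
    return np.clip(blended, 0, 255).astype(np.uint8)
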