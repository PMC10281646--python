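"""Pluggable CNN backbones, transfer-style fine-tuning, and GAP features.

A backbone is a :class:`~lesionfuse.nn.Sequential` ending in a global
average pooling (GAP) layer followed by a three-layer classification
head (dense, softmax, classification output).  Fine-tuning deletes that
head, attaches a fresh dense layer of width ``n_classes`` plus softmax
and output layers, and retrains all layers on a stratified split of the
target images.  Deep features are then read at the GAP layer — one
value per channel of the last convolutional block, i.e. the spatial
mean of each activation map — rather than at the fully-connected layer.

Three presets are registered:

``xception_gap``
    A compact depthwise-separable convolution stack whose GAP width is
    2048 channels, the feature width this pipeline calls FV1.
``shufflenet_gap``
    A lighter separable stack with GAP width 544 channels (FV2).
``tinycnn``
    A two-conv test-scale backbone with configurable GAP width, small
    enough to fine-tune in seconds on synthetic image sets.

Preset weights are randomly initialized from the construction seed;
externally trained weights can be loaded onto any preset through the
layer parameter arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .nn import (
    ClassOutput,
    Conv2d,
    Dense,
    GlobalAvgPool,
    MaxPool2d,
    ReLU,
    RMSProp,
    SeparableConv2d,
    Sequential,
    Softmax,
    train_classifier,
)
from .synthetic import LabeledImageSet

__all__ = [
    "BackboneSpec",
    "FineTuneConfig",
    "FeatureMatrix",
    "SplitRecord",
    "BACKBONE_PRESETS",
    "build_backbone",
    "build_finetune_head",
    "fine_tune",
    "extract_features",
    "images_to_tensor",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Declares a backbone's identity, input size, GAP layer and width."""

    name: str
    input_size: int
    gap_layer: str
    feature_width: int
    source_tag: str = "synthetic"

    def __post_init__(self):
        if self.feature_width < 1:
            raise InvalidArgumentError("feature_width must be positive")


@dataclass
class FineTuneConfig:
    """Transfer-learning hyperparameters.

    The defaults are the pipeline's training recipe: 3 epochs of RMSProp
    at learning rate 1e-4 with mini-batches of 16, on a stratified
    50:50 train/test split of the target images.
    """

    epochs: int = 3
    learning_rate: float = 1e-4
    optimizer: str = "rmsprop"
    batch_size: int = 16
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidArgumentError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.optimizer != "rmsprop":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeatureMatrix:
    """An ``N x D`` deep-feature matrix with sample ids and labels."""

    values: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    source: str = "synthetic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        # width 0 is tolerated so fusing with an empty block is the identity
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise InvalidArgumentError("values must be a non-empty N x D matrix")
        if not np.isfinite(self.values).all():
            raise InvalidArgumentError("feature matrix contains non-finite entries")
        if len(self.sample_ids) != self.values.shape[0]:
            raise InvalidArgumentError("sample_ids must align with rows")
        if self.labels.shape[0] != self.values.shape[0]:
            raise InvalidArgumentError("labels must align with rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = [f"f{j:04d}" for j in range(self.width)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str = "synthetic") -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f")]
        return cls(
            df[feat_cols].to_numpy(float),
            df["sample_id"].astype(str).tolist(),
            df["label"].to_numpy(int),
            source,
        )


@dataclass
class SplitRecord:
    """The stratified train/test partition used during fine-tuning."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# preset architectures


def _build_tinycnn(rng: np.random.Generator, gap_width: int = 8, head: int = 10):
    return Sequential(
        [
            Conv2d(3, 8, 3, 1, "same", rng, name="conv1"),
            ReLU(name="relu1"),
            MaxPool2d(2, name="pool1"),
            Conv2d(8, gap_width, 3, 1, "same", rng, name="conv_final"),
            ReLU(name="relu_final"),
            GlobalAvgPool(name="gap"),
            Dense(gap_width, head, rng, name="fc"),
            Softmax(name="softmax"),
            ClassOutput(name="classoutput"),
        ]
    )


def _build_xception_gap(rng: np.random.Generator, head: int = 1000):
    """Separable-conv stack reaching a 2048-channel GAP layer.

    Channel widths follow the entry/middle/exit progression of extreme-
    inception style networks (…728 → 1024 → 1536 → 2048) at reduced
    depth so that random-weight instantiation and feature extraction
    run at desk scale.
    """
    return Sequential(
        [
            Conv2d(3, 32, 3, 2, "same", rng, name="entry_conv"),
            ReLU(name="entry_relu"),
            SeparableConv2d(32, 64, 3, 1, "same", rng, name="sep1"),
            ReLU(name="relu1"),
            SeparableConv2d(64, 128, 3, 2, "same", rng, name="sep2"),
            ReLU(name="relu2"),
            SeparableConv2d(128, 256, 3, 2, "same", rng, name="sep3"),
            ReLU(name="relu3"),
            SeparableConv2d(256, 728, 3, 2, "same", rng, name="sep_mid"),
            ReLU(name="relu_mid"),
            SeparableConv2d(728, 1024, 3, 2, "same", rng, name="sep_exit1"),
            ReLU(name="relu_exit1"),
            SeparableConv2d(1024, 1536, 3, 1, "same", rng, name="sep_exit2"),
            ReLU(name="relu_exit2"),
            SeparableConv2d(1536, 2048, 3, 1, "same", rng, name="sep_exit3"),
            ReLU(name="relu_exit3"),
            GlobalAvgPool(name="avg1"),
            Dense(2048, head, rng, name="fc"),
            Softmax(name="softmax"),
            ClassOutput(name="classoutput"),
        ]
    )


def _build_shufflenet_gap(rng: np.random.Generator, head: int = 1000):
    """Light separable stack reaching a 544-channel GAP layer."""
    return Sequential(
        [
            Conv2d(3, 24, 3, 2, "same", rng, name="entry_conv"),
            ReLU(name="entry_relu"),
            MaxPool2d(2, name="entry_pool"),
            SeparableConv2d(24, 136, 3, 1, "same", rng, name="stage2"),
            ReLU(name="relu2"),
            SeparableConv2d(136, 272, 3, 2, "same", rng, name="stage3"),
            ReLU(name="relu3"),
            SeparableConv2d(272, 544, 3, 2, "same", rng, name="stage4"),
            ReLU(name="relu4"),
            GlobalAvgPool(name="node_200"),
            Dense(544, head, rng, name="fc"),
            Softmax(name="softmax"),
            ClassOutput(name="classoutput"),
        ]
    )


BACKBONE_PRESETS: dict[str, BackboneSpec] = {
    "tinycnn": BackboneSpec("tinycnn", 32, "gap", 8, "synthetic"),
    "xception": BackboneSpec("xception", 64, "avg1", 2048, "FV1"),
    "shufflenet": BackboneSpec("shufflenet", 64, "node_200", 544, "FV2"),
}

_BUILDERS = {
    "tinycnn": _build_tinycnn,
    "xception": _build_xception_gap,
    "shufflenet": _build_shufflenet_gap,
}


def build_backbone(
    name: str, seed: int = 0, gap_width: int | None = None
) -> tuple[Sequential, BackboneSpec]:
    """Instantiate a preset backbone with seed-determined weights.

    ``gap_width`` reconfigures the tinycnn fixture only; the xception
    and shufflenet presets have fixed GAP widths of 2048 and 544.
    """
    if name not in _BUILDERS:
        raise ConfigurationError(
            f"unknown backbone {name!r}; known: {sorted(_BUILDERS)}"
        )
    rng = np.random.default_rng(seed)
    spec = BACKBONE_PRESETS[name]
    if name == "tinycnn" and gap_width is not None:
        model = _build_tinycnn(rng, gap_width=gap_width)
        spec = BackboneSpec("tinycnn", 32, "gap", gap_width, "synthetic")
    elif gap_width is not None:
        raise ConfigurationError(f"gap_width is only configurable for tinycnn")
    else:
        model = _BUILDERS[name](rng)
    return model, spec


def build_finetune_head(
    model: Sequential, spec: BackboneSpec, n_classes: int, seed: int = 0
) -> Sequential:
    """Replace the final three layers with a fresh ``n_classes``-way head.

    The deleted layers are the dense prediction layer, the softmax and
    the classification output; everything before the GAP layer keeps
    its weights, so the network is initialized from the source task and
    only re-trained on the target one.
    """
    if n_classes < 2:
        raise ConfigurationError("n_classes must be >= 2")
    if len(model.layers) < 3:
        raise ConfigurationError("model too shallow to carry a 3-layer head")
    rng = np.random.default_rng(seed)
    body = model.layers[:-3]
    gap_width = spec.feature_width
    return Sequential(
        body
        + [
            Dense(gap_width, n_classes, rng, name="fc_new"),
            Softmax(name="softmax_new"),
            ClassOutput(name="classoutput_new"),
        ]
    )


def images_to_tensor(images: list[np.ndarray]) -> np.ndarray:
    """Stack H x W x 3 uint8 images into a float32 ``(N, 3, H, W)`` tensor in [0, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> SplitRecord:
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return SplitRecord(np.sort(np.array(train)), np.sort(np.array(test)), seed)


def fine_tune(
    model: Sequential, ds: LabeledImageSet, cfg: FineTuneConfig
) -> tuple[Sequential, SplitRecord]:
    """Train all layers on a stratified split of ``ds``; returns the split too.

    The split is recorded so downstream evaluation can reuse the same
    partition.  Training is mini-batch RMSProp on cross-entropy and is
    deterministic for a fixed ``cfg.seed``.
    """
    labels = np.asarray(ds.labels)
    for c, size in enumerate(ds.class_sizes()):
        if size < 2:
            raise InvalidArgumentError(
                f"class {ds.class_names[c]!r} has {size} image(s); need >= 2"
            )
    split = stratified_split(labels, cfg.train_fraction, cfg.seed)
    x = images_to_tensor([ds.images[i] for i in split.train_idx])
    y = labels[split.train_idx]
    opt = RMSProp(lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    train_classifier(model, x, y, cfg.epochs, cfg.batch_size, opt, rng)
    return model, split


def extract_features(
    model: Sequential,
    ds: LabeledImageSet,
    spec: BackboneSpec,
    batch_size: int = 32,
) -> FeatureMatrix:
    """Read the GAP layer for every image of ``ds``, in dataset order."""
    try:
        gap_idx = model.find(spec.gap_layer)
    except ConfigurationError:
        raise ConfigurationError(
            f"backbone has no layer {spec.gap_layer!r}; layers: "
            f"{[n for n in model.layer_names() if n]}"
        )
    rows = []
    for start in range(0, len(ds), batch_size):
        x = images_to_tensor(ds.images[start : start + batch_size])
        for lay in model.layers[: gap_idx + 1]:
            x = lay.forward(x, train=False)
        rows.append(np.asarray(x, dtype=float))
    values = np.concatenate(rows, axis=0)
    if values.shape[1] != spec.feature_width:
        raise ConfigurationError(
            f"GAP width {values.shape[1]} != declared feature_width "
            f"{spec.feature_width}"
        )
    ids = [f"s{i:05d}" for i in range(len(ds))]
    return FeatureMatrix(values, ids, np.asarray(ds.labels), spec.source_tag)
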