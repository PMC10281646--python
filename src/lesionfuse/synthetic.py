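"""Synthetic fixtures with known ground truth.

Two generators back the test and demo path of the pipeline:

* :func:`make_image_set` draws a multi-class set of lesion-like images:
  a textured background with one colored, textured elliptical blob per
  image whose color/stripe signature is class-specific.  The blob
  bounding box is recorded per image so saliency maps can be checked
  against a known "important region".
* :func:`make_feature_table` plants an informative column subset among
  independent Gaussian noise columns, so feature-selection runs can be
  scored against the planted mask and against an exhaustive-search
  optimum.

Both are deterministic for a fixed seed, with no global random state.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidArgumentError

__all__ = [
    "LabeledImageSet",
    "PlantedFeatureTable",
    "make_image_set",
    "make_feature_table",
    "save_image_set",
    "load_image_set",
    "save_feature_table",
    "load_feature_table",
]


@dataclass
class LabeledImageSet:
    """A class-labeled RGB image collection.

    Parameters
    ----------
    images
        List of ``H x W x 3`` uint8 arrays.  Heights/widths may differ
        between images; the channel count is always 3.
    labels
        One class index per image, indexing into ``class_names``.
    class_names
        Human-readable class names.
    bboxes
        Optional per-image ``(row0, col0, row1, col1)`` half-open
        bounding box of the lesion-like blob (synthetic sets only).
    """

    images: list[np.ndarray]
    labels: list[int]
    class_names: list[str]
    bboxes: list[tuple[int, int, int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise InvalidArgumentError("images and labels must have equal length")
        for im in self.images:
            if im.ndim != 3 or im.shape[2] != 3:
                raise InvalidArgumentError("every image must be H x W x 3")
            if im.shape[0] < 8 or im.shape[1] < 8:
                raise InvalidArgumentError("images must be at least 8 x 8")
        for lab in self.labels:
            if not 0 <= lab < len(self.class_names):
                raise InvalidArgumentError(f"label {lab} outside class_names")
        if self.bboxes is not None and len(self.bboxes) != len(self.images):
            raise InvalidArgumentError("bboxes must align with images")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_sizes(self) -> list[int]:
        counts = [0] * self.n_classes
        for lab in self.labels:
            counts[lab] += 1
        return counts


@dataclass
class PlantedFeatureTable:
    """An ``N x D`` feature matrix with a known informative column subset."""

    matrix: np.ndarray
    labels: np.ndarray
    informative_mask: np.ndarray
    seed: int
    class_sep: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
        if self.matrix.ndim != 2:
            raise InvalidArgumentError("matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise InvalidArgumentError("labels must align with matrix rows")
        if self.matrix.shape[1] != self.informative_mask.shape[0]:
            raise InvalidArgumentError("informative_mask must align with columns")
        if not self.informative_mask.any():
            raise InvalidArgumentError("at least one informative column required")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _class_palette(n_classes: int) -> list[tuple[np.ndarray, int]]:
    """Per-class (RGB color, stripe period) blob signatures.

    Hues are evenly spaced around the color wheel and stripe periods
    alternate so adjacent hues also differ in texture.
    """
    palette = []
    for c in range(n_classes):
        hue = c / n_classes
        r, g, b = colorsys.hsv_to_rgb(hue, 0.9, 0.9)
        color = np.array([r, g, b]) * 255.0
        period = 3 + 2 * (c % 3)
        palette.append((color, period))
    return palette


def make_image_set(
    n_classes: int, per_class: int, size: int, seed: int
) -> LabeledImageSet:
    """Generate ``n_classes * per_class`` blob images of shape ``size x size x 3``.

    Each class has a distinct blob color and stripe texture.  Blob
    position and radii vary per image; the bounding box of each blob is
    recorded.  Deterministic for a fixed seed.
    """
    if n_classes < 2 or per_class < 1 or size < 16:
        raise InvalidArgumentError(
            "need n_classes >= 2, per_class >= 1, size >= 16"
        )
    rng = np.random.default_rng(seed)
    palette = _class_palette(n_classes)
    images: list[np.ndarray] = []
    labels: list[int] = []
    bboxes: list[tuple[int, int, int, int]] = []
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    for c in range(n_classes):
        color, period = palette[c]
        for _ in range(per_class):
            bg = 70.0 + rng.normal(0.0, 8.0, size=(size, size, 1))
            img = np.repeat(bg, 3, axis=2)
            # blob geometry: ellipse well inside the frame
            ry = rng.uniform(size / 6.5, size / 4.0)
            rx = rng.uniform(size / 6.5, size / 4.0)
            cy = rng.uniform(ry + 1, size - ry - 1)
            cx = rng.uniform(rx + 1, size - rx - 1)
            theta = rng.uniform(0, np.pi)
            dy, dx = rows - cy, cols - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            stripes = 0.75 + 0.25 * np.sin(2 * np.pi * u / period)
            blob = color[None, None, :] * stripes[:, :, None]
            img[inside] = blob[inside]
            img += rng.normal(0.0, 3.0, size=img.shape)
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(c)
            r0 = max(int(np.floor(cy - max(ry, rx))), 0)
            c0 = max(int(np.floor(cx - max(ry, rx))), 0)
            r1 = min(int(np.ceil(cy + max(ry, rx))) + 1, size)
            c1 = min(int(np.ceil(cx + max(ry, rx))) + 1, size)
            bboxes.append((r0, c0, r1, c1))
    names = [f"class_{c}" for c in range(n_classes)]
    return LabeledImageSet(images, labels, names, bboxes)


def make_feature_table(
    n: int,
    d_informative: int,
    d_noise: int,
    n_classes: int,
    class_sep: float,
    seed: int,
) -> PlantedFeatureTable:
    """Plant ``d_informative`` signal columns among ``d_noise`` noise columns.

    Informative column ``j`` carries a mean shift of ``class_sep`` for
    classes ``c`` with ``(j - c) % n_classes == 0`` (a cyclic one-hot
    pattern), so no single column separates all classes but the planted
    subset jointly does; unit-variance Gaussian noise is added.  Noise
    columns are standard Gaussian, independent of the label.  Labels are
    assigned round-robin, hence exactly uniform when ``n_classes``
    divides ``n``.
    """
    if d_informative < 1:
        raise InvalidArgumentError("d_informative must be >= 1")
    if n < 2 * n_classes:
        raise InvalidArgumentError("need n >= 2 * n_classes")
    if n_classes < 2:
        raise InvalidArgumentError("need n_classes >= 2")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    d = d_informative + d_noise
    matrix = rng.standard_normal((n, d))
    for j in range(d_informative):
        hot = (labels % n_classes) == (j % n_classes)
        matrix[hot, j] += class_sep
    mask = np.zeros(d, dtype=bool)
    mask[:d_informative] = True
    return PlantedFeatureTable(matrix, labels, mask, seed, class_sep)


# ---------------------------------------------------------------------------
# plain-text / PNG serialization


def save_image_set(ds: LabeledImageSet, root: str | Path) -> None:
    """Write a directory-per-class PNG tree (plus a bbox JSON if present)."""
    root = Path(root)
    counters = [0] * ds.n_classes
    meta: dict[str, list] = {"class_names": ds.class_names, "bboxes": []}
    for img, lab in zip(ds.images, ds.labels):
        cls_dir = root / ds.class_names[lab]
        cls_dir.mkdir(parents=True, exist_ok=True)
        name = f"img_{counters[lab]:05d}.png"
        Image.fromarray(img).save(cls_dir / name)
        counters[lab] += 1
    if ds.bboxes is not None:
        meta["bboxes"] = [list(b) for b in ds.bboxes]
        meta["labels"] = list(ds.labels)
        (root / "metadata.json").write_text(json.dumps(meta))


def load_image_set(root: str | Path) -> LabeledImageSet:
    """Read a directory-per-class PNG tree written by :func:`save_image_set`."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise InvalidArgumentError(f"no class directories under {root}")
    images, labels = [], []
    names = [p.name for p in class_dirs]
    for lab, cls_dir in enumerate(class_dirs):
        for f in sorted(cls_dir.glob("*.png")):
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(lab)
    return LabeledImageSet(images, labels, names)


def save_feature_table(table: PlantedFeatureTable, csv_path: str | Path) -> None:
    """CSV with header ``sample_id,label,f0000..``; JSON sidecar with the mask."""
    csv_path = Path(csv_path)
    d = table.n_features
    cols = [f"f{j:04d}" for j in range(d)]
    df = pd.DataFrame(table.matrix, columns=cols)
    df.insert(0, "label", table.labels)
    df.insert(0, "sample_id", [f"s{i:05d}" for i in range(len(table.labels))])
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "informative_mask": table.informative_mask.astype(int).tolist(),
                "seed": table.seed,
                "class_sep": table.class_sep,
            }
        )
    )


def load_feature_table(csv_path: str | Path) -> PlantedFeatureTable:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    feat_cols = [c for c in df.columns if c.startswith("f")]
    return PlantedFeatureTable(
        df[feat_cols].to_numpy(float),
        df["label"].to_numpy(int),
        np.asarray(meta["informative_mask"], bool),
        int(meta["seed"]),
        float(meta.get("class_sep", 0.0)),
    )
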