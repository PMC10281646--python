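"""Geometric augmentation and per-class balancing.

The augmentation vocabulary is the one the pipeline's dataset-balancing
stage uses: transpose, vertical flip (row order reversed, the 0-based
equivalent of mapping row ``a`` to ``m + 1 - a`` in 1-based notation),
horizontal flip (column order reversed), and exact 90-degree rotation
realized as an index permutation — no interpolation ever happens.

These four operators generate the 8-element dihedral symmetry group of
the pixel grid, which bounds how many distinct variants one original can
yield; :func:`balance_class` oversamples a class to a target count by
cycling deterministically through the seven non-identity symmetries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .synthetic import LabeledImageSet

__all__ = [
    "AugmentationPlan",
    "transpose_image",
    "flip_vertical",
    "flip_horizontal",
    "rotate90",
    "balance_class",
    "augment_dataset",
    "VARIANT_OPS",
]


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidArgumentError("expected an H x W x 3 image")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise InvalidArgumentError("empty image")
    return img


def transpose_image(img: np.ndarray) -> np.ndarray:
    """Swap rows and columns; channels untouched: ``out[b, a, c] = in[a, b, c]``."""
    img = _check_image(img)
    return np.ascontiguousarray(img.transpose(1, 0, 2))


def flip_vertical(img: np.ndarray) -> np.ndarray:
    """Reverse row order (top row becomes bottom row)."""
    img = _check_image(img)
    return np.ascontiguousarray(img[::-1, :, :])


def flip_horizontal(img: np.ndarray) -> np.ndarray:
    """Reverse column order (left column becomes right column)."""
    img = _check_image(img)
    return np.ascontiguousarray(img[:, ::-1, :])


def rotate90(img: np.ndarray, k: int = 1) -> np.ndarray:
    """Rotate by ``k`` counter-clockwise quarter turns (``k`` reduced mod 4).

    The rotation is the exact index permutation induced by the 2-D
    rotation matrix at multiples of 90 degrees on homogeneous pixel
    coordinates; ``k = 0`` is the identity.
    """
    img = _check_image(img)
    return np.ascontiguousarray(np.rot90(img, k % 4, axes=(0, 1)))


def _bbox_flip_v(b, h, w):
    r0, c0, r1, c1 = b
    return (h - r1, c0, h - r0, c1)


def _bbox_flip_h(b, h, w):
    r0, c0, r1, c1 = b
    return (r0, w - c1, r1, w - c0)


def _bbox_rot90(b, h, w):
    # CCW quarter turn: pixel (r, c) -> (w - 1 - c, r); output is w x h
    r0, c0, r1, c1 = b
    return (w - c1, r0, w - c0, r1)


# The seven distinct non-identity symmetries of the pixel grid, as
# (name, image transform, bbox transform) in the deterministic
# oversampling order.  flip_v∘flip_h coincides with a 180° rotation, so
# compositions are listed once each.
def _compose(f, g):
    return lambda x: f(g(x))


def _bbox_compose(fb, gb, g_swaps):
    def run(b, h, w):
        b2 = gb(b, h, w)
        h2, w2 = (w, h) if g_swaps else (h, w)
        return fb(b2, h2, w2)

    return run


VARIANT_OPS: list[tuple[str, object, object, bool]] = [
    ("flip_v", flip_vertical, _bbox_flip_v, False),
    ("flip_h", flip_horizontal, _bbox_flip_h, False),
    ("rot90", rotate90, _bbox_rot90, True),
    (
        "rot180",
        lambda x: rotate90(x, 2),
        _bbox_compose(_bbox_rot90, _bbox_rot90, True),
        False,
    ),
    (
        "flip_v+rot90",
        _compose(flip_vertical, rotate90),
        _bbox_compose(_bbox_flip_v, _bbox_rot90, True),
        True,
    ),
    (
        "flip_h+rot90",
        _compose(flip_horizontal, rotate90),
        _bbox_compose(_bbox_flip_h, _bbox_rot90, True),
        True,
    ),
    (
        "rot270",
        lambda x: rotate90(x, 3),
        _bbox_compose(
            _bbox_rot90, _bbox_compose(_bbox_rot90, _bbox_rot90, True), False
        ),
        True,
    ),
]


@dataclass
class AugmentationPlan:
    """Which operators balance uses and the per-class target count."""

    target_per_class: int
    ops: tuple[str, ...] = ("flip_vertical", "flip_horizontal", "rotate90")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ops:
            raise InvalidArgumentError("ops must be non-empty")
        known = {"flip_vertical", "flip_horizontal", "rotate90", "transpose"}
        for op in self.ops:
            if op not in known:
                raise InvalidArgumentError(f"unknown augmentation op {op!r}")
        if self.target_per_class < 1:
            raise InvalidArgumentError("target_per_class must be >= 1")


def balance_class(
    images: list[np.ndarray],
    target: int,
    plan: AugmentationPlan,
    bboxes: list[tuple[int, int, int, int]] | None = None,
):
    """Grow (or keep) a class to exactly ``target`` images.

    Originals are retained first; extras cycle through the seven
    non-identity grid symmetries, each applied to the originals in
    order, until the target is reached.  Fully deterministic.  At most
    ``8 * len(images)`` distinct variants exist, and the function
    refuses targets beyond that bound rather than emit duplicates.

    Returns the image list, or ``(images, bboxes)`` when ``bboxes`` is
    given (boxes are transformed alongside their images).
    """
    if not images:
        raise InvalidArgumentError("cannot balance an empty class")
    if target < 1:
        raise InvalidArgumentError("target must be >= 1")
    n = len(images)
    if target <= n:
        # balancing never discards: classes at or above target pass through
        if bboxes is not None:
            return list(images), list(bboxes)
        return list(images)
    if target > 8 * n:
        raise InvalidArgumentError(
            f"target {target} exceeds the {8 * n} distinct symmetry variants "
            f"of {n} originals"
        )
    out_imgs = list(images)
    out_boxes = list(bboxes) if bboxes is not None else None
    needed = target - n
    made = 0
    for _, img_op, box_op, _swaps in VARIANT_OPS:
        for i in range(n):
            if made == needed:
                break
            out_imgs.append(img_op(images[i]))
            if out_boxes is not None:
                h, w = images[i].shape[:2]
                out_boxes.append(box_op(bboxes[i], h, w))
            made += 1
        if made == needed:
            break
    if out_boxes is not None:
        return out_imgs, out_boxes
    return out_imgs


def augment_dataset(ds: LabeledImageSet, plan: AugmentationPlan) -> LabeledImageSet:
    """Balance every class of ``ds`` to ``plan.target_per_class`` images.

    Classes already at or above the target are kept as-is; class names
    are unchanged and bounding boxes, when present, are carried through
    the geometric transforms.
    """
    per_class_imgs: list[list[np.ndarray]] = [[] for _ in ds.class_names]
    per_class_boxes: list[list] = [[] for _ in ds.class_names]
    for i, lab in enumerate(ds.labels):
        per_class_imgs[lab].append(ds.images[i])
        if ds.bboxes is not None:
            per_class_boxes[lab].append(ds.bboxes[i])
    images: list[np.ndarray] = []
    labels: list[int] = []
    boxes: list | None = [] if ds.bboxes is not None else None
    for c, imgs in enumerate(per_class_imgs):
        if not imgs:
            raise InvalidArgumentError(f"class {ds.class_names[c]!r} is empty")
        tgt = max(plan.target_per_class, len(imgs))
        if ds.bboxes is not None:
            bal, bal_boxes = balance_class(imgs, tgt, plan, per_class_boxes[c])
            boxes.extend(bal_boxes)
        else:
            bal = balance_class(imgs, tgt, plan)
        images.extend(bal)
        labels.extend([c] * len(bal))
    return LabeledImageSet(images, labels, list(ds.class_names), boxes)
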