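"""Serial feature fusion: column-wise concatenation of two feature spaces.

If one backbone yields a ``k``-dimensional vector per sample and a
second yields an ``n``-dimensional one, the serial combination is the
``(k + n)``-dimensional concatenation — no value is scaled, reweighted
or otherwise transformed, and the original blocks remain recoverable by
column slicing.  Alignment is enforced by sample id, never inferred
from row position alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbones import FeatureMatrix
from .errors import AlignmentError

__all__ = ["FusedFeatureMatrix", "serial_fuse"]


@dataclass
class FusedFeatureMatrix(FeatureMatrix):
    """A fused matrix remembering where its source blocks begin and end."""

    block_boundaries: tuple[int, int] = (0, 0)
    provenance: tuple[str, str] = ("", "")

    def block(self, which: int) -> np.ndarray:
        """Return source block 0 or 1 as a column slice (exact values)."""
        k, kn = self.block_boundaries
        if which == 0:
            return self.values[:, :k]
        if which == 1:
            return self.values[:, k:kn]
        raise IndexError("block index must be 0 or 1")


def serial_fuse(fv1: FeatureMatrix, fv2: FeatureMatrix) -> FusedFeatureMatrix:
    """Concatenate ``fv1`` (width k) and ``fv2`` (width n) into width k + n.

    Raises :class:`AlignmentError` if the two matrices do not list the
    same samples in the same order with the same labels; rows are never
    silently reordered.
    """
    if fv1.sample_ids != fv2.sample_ids:
        raise AlignmentError("sample_ids differ between the two feature matrices")
    if not np.array_equal(fv1.labels, fv2.labels):
        raise AlignmentError("labels differ between the two feature matrices")
    values = np.concatenate([fv1.values, fv2.values], axis=1)
    k = fv1.width
    return FusedFeatureMatrix(
        values=values,
        sample_ids=list(fv1.sample_ids),
        labels=fv1.labels.copy(),
        source="fused",
        block_boundaries=(k, k + fv2.width),
        provenance=(fv1.source, fv2.source),
    )
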