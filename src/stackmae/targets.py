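"""Dense training targets derived from instance labels.

Two target families are supported, matching the two fine-tuning tasks:

* nearest-neighbor *affinity maps* — 3 channels (z, y, x offsets), channel
  ``c`` at voxel ``v`` is 1 iff ``v`` and its neighbor ``v - e_c`` carry the
  same nonzero label;
* *BCD maps* — foreground binary map, instance contour map, and a
  per-instance Euclidean distance-to-boundary normalized to [0, 1] by each
  instance's maximum (so large and small instances contribute comparably).

Both are pure functions of label geometry: bijectively relabeling the
instances leaves every target unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

_STRUCT_XY = np.zeros((1, 3, 3), dtype=bool)
_STRUCT_XY[0] = [[False, True, False], [True, True, True], [False, True, False]]


@dataclass
class AffinityMap:
    """3-channel nearest-neighbor affinities, axes (c, z, y, x)."""

    data: np.ndarray  # (3, Z, Y, X), {0,1} for targets / [0,1] for predictions

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(f"expected (3, Z, Y, X), got {self.data.shape}")


@dataclass
class BCDTarget:
    """Binary / contour / distance target stack, axes (c, z, y, x)."""

    binary: np.ndarray
    contour: np.ndarray
    distance: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack(
            [self.binary, self.contour, self.distance], axis=0
        ).astype(np.float32)


def affinity_from_labels(labels: LabelVolume) -> AffinityMap:
    """Nearest-neighbor affinities; boundary-of-volume entries are 0."""
    lab = labels.data
    aff = np.zeros((3,) + lab.shape, dtype=np.float32)
    for c in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[c] = slice(1, None)
        b[c] = slice(None, -1)
        same = (lab[tuple(a)] == lab[tuple(b)]) & (lab[tuple(a)] != 0)
        aff[(c, *a)] = same
    return AffinityMap(aff)


def _boundary_voxels(lab: np.ndarray) -> np.ndarray:
    """Foreground voxels with a different-labeled in-volume 6-neighbor.

    Out-of-volume voxels are *not* treated as background, so instances
    touching a volume face grow no contour there.
    """
    out = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(1, None)
        b[axis] = slice(None, -1)
        diff = lab[tuple(a)] != lab[tuple(b)]
        out[tuple(a)] |= diff
        out[tuple(b)] |= diff
    return out & (lab > 0)


def bcd_from_labels(labels: LabelVolume, contour_width: int = 1) -> BCDTarget:
    """Binary, contour and normalized-distance maps from instance labels.

    Contours are seeded from 6-neighborhood label changes and widened
    in-plane only (``contour_width`` > 1), respecting the stack anisotropy.
    """
    if contour_width < 1:
        raise ValueError("contour_width must be >= 1")
    lab = labels.data
    binary = (lab > 0).astype(np.float32)
    contour = _boundary_voxels(lab)
    if contour_width > 1:
        contour = ndimage.binary_dilation(
            contour, structure=_STRUCT_XY, iterations=contour_width - 1
        )
        contour &= lab > 0
    distance = np.zeros(lab.shape, dtype=np.float32)
    for inst in labels.ids():
        mask = lab == inst
        d = ndimage.distance_transform_edt(mask)
        dmax = d.max()
        if dmax > 0:
            distance[mask] = d[mask] / dmax
    return BCDTarget(binary, contour.astype(np.float32), distance)
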