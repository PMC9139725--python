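"""Crop a chest CT to the thoracic region using a classical lung mask.

The lungs are found as internal air (below -500 HU, not connected to the
array border); the crop box is their axis-aligned bounding box dilated by a
symmetric physical margin.  HU values are never altered — cropping is a pure
array slice applied identically to the CT and any co-registered masks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, SegMask

#: Threshold separating aerated lung from soft tissue.
LUNG_HU_THRESHOLD = -500.0
DEFAULT_MARGIN_MM = 20.0


@dataclass(frozen=True)
class CropBox:
    """Inclusive per-axis voxel index ranges of a crop, with its margin."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]
    margin_mm: float

    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.x[0], self.x[1] + 1),
            slice(self.y[0], self.y[1] + 1),
            slice(self.z[0], self.z[1] + 1),
        )

    def as_dict(self) -> dict:
        return asdict(self)


def extract_lung_mask(ct: CTVolume) -> SegMask:
    """Segment the lungs by thresholding internal air.

    Voxels below -500 HU whose connected component does not touch the array
    border are candidate lung; the two largest components are kept.  If no
    internal air exists the mask is empty and a warning is emitted.
    """
    air = ct.data < LUNG_HU_THRESHOLD
    labels, n = ndimage.label(air)
    if n == 0:
        warnings.warn("no air below -500 HU found; lung mask is empty", stacklevel=2)
        return SegMask(np.zeros(ct.shape, np.uint8), ct.spacing, label="prediction")

    border = np.zeros(ct.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border & air])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[touching] = 0
    internal = np.flatnonzero(counts)
    if internal.size == 0:
        warnings.warn("no internal air component found; lung mask is empty", stacklevel=2)
        return SegMask(np.zeros(ct.shape, np.uint8), ct.spacing, label="prediction")
    keep = internal[np.argsort(counts[internal])[::-1][:2]]
    lung = np.isin(labels, keep)
    return SegMask(lung.astype(np.uint8), ct.spacing, label="prediction")


def crop_to_chest(
    ct: CTVolume,
    masks: list[SegMask] | None = None,
    margin_mm: float = DEFAULT_MARGIN_MM,
    lung_mask: SegMask | None = None,
) -> tuple[CTVolume, list[SegMask], CropBox]:
    """Crop the CT (and any masks) to the lung bounding box plus a margin.

    The margin is converted to voxels per axis with ceiling rounding and the
    box is clamped to the grid.  With an empty lung mask the inputs are
    returned uncropped with a warning.
    """
    masks = list(masks) if masks else []
    if lung_mask is None:
        lung_mask = extract_lung_mask(ct)
    if lung_mask.n_voxels == 0:
        warnings.warn("empty lung mask; returning input uncropped", stacklevel=2)
        full = CropBox(
            (0, ct.shape[0] - 1), (0, ct.shape[1] - 1), (0, ct.shape[2] - 1),
            margin_mm,
        )
        return ct, masks, full

    nz = np.nonzero(lung_mask.data)
    lo, hi = [], []
    for axis in range(3):
        m = math.ceil(margin_mm / ct.spacing[axis])
        lo.append(max(0, int(nz[axis].min()) - m))
        hi.append(min(ct.shape[axis] - 1, int(nz[axis].max()) + m))
    box = CropBox((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]), margin_mm)
    sl = box.slices()
    cropped_ct = CTVolume(ct.data[sl], ct.spacing, affine=ct.affine)
    cropped_masks = [
        SegMask(m.data[sl], m.spacing, label=m.label, affine=m.affine) for m in masks
    ]
    return cropped_ct, cropped_masks, box
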