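"""NIfTI input/output and the basic image containers.

A :class:`CTVolume` is a 3-D grid of Hounsfield-unit (HU) values with a
physical voxel spacing in millimetres; a :class:`SegMask` is a binary grid on
the same voxel lattice.  No resampling or reorientation is ever performed
silently: any shape or spacing disagreement between a mask and its reference
volume raises :class:`~pefquant.errors.GridMismatchError`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GridMismatchError

logger = logging.getLogger(__name__)

#: HU values outside this range are physically implausible on clinical CT and
#: trigger a warning (not an error) on load/construction.
PLAUSIBLE_HU_RANGE = (-1100.0, 3100.0)

_VALID_MASK_LABELS = frozenset(
    {"reference", "prediction", "reader1", "reader2", "truth"}
)


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


@dataclass
class CTVolume:
    """A 3-D CT attenuation volume.

    Parameters
    ----------
    data
        3-D array of HU values.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    affine
        4x4 voxel-to-world matrix carried from (and back to) the NIfTI
        header; purely metadata, never used to resample.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"CT volume must be 3-D, got {self.data.ndim}-D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        if not np.all(np.isfinite(np.asarray(self.data, dtype=np.float64))):
            raise ValueError("HU values must be finite")
        lo, hi = PLAUSIBLE_HU_RANGE
        dmin, dmax = float(self.data.min()), float(self.data.max())
        if dmin < lo or dmax > hi:
            warnings.warn(
                f"HU range [{dmin:.0f}, {dmax:.0f}] outside plausible clinical "
                f"range [{lo:.0f}, {hi:.0f}]",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class SegMask:
    """A binary segmentation mask on the grid of a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "reference"
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"mask must be 3-D, got {self.data.ndim}-D"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, got {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm values, got {self.spacing}")
        if self.label not in _VALID_MASK_LABELS:
            raise ValueError(
                f"label must be one of {sorted(_VALID_MASK_LABELS)}, got {self.label!r}"
            )
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        """Number of foreground voxels."""
        return int(np.count_nonzero(self.data))


def check_same_grid(a: CTVolume | SegMask, b: CTVolume | SegMask) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share shape and spacing."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-5, atol=1e-6):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def voxel_volume_ml(spacing: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in mL (= cm^3) for a spacing in mm."""
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return float(spacing[0]) * float(spacing[1]) * float(spacing[2]) / 1000.0


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3-D image, got {data.ndim}-D"
        )
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    return data, spacing, np.asarray(img.affine)


def load_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI-1/2 file (.nii or .nii.gz)."""
    data, spacing, affine = _load_nifti(path)
    return CTVolume(data=data, spacing=spacing, affine=affine)


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CT volume to NIfTI, preserving dtype bit-exactly."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: CTVolume) -> SegMask:
    """Read a binary mask and check it against the reference CT grid.

    Nonzero values other than 1 are coerced to 1 with a logged note.
    """
    data, spacing, affine = _load_nifti(path)
    if np.any((data != 0) & (data != 1)):
        logger.warning(
            "%s: nonzero mask values other than 1 coerced to 1", Path(path).name
        )
        data = (data != 0).astype(np.uint8)
    mask = SegMask(data=data.astype(np.uint8), spacing=spacing, affine=affine)
    check_same_grid(mask, reference)
    return mask


def save_mask(mask: SegMask, path: str | Path) -> None:
    """Write a binary mask to NIfTI as unsigned 8-bit."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
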