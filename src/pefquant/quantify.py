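"""Per-case pericardial-effusion quantification and rule-based classification.

Given a CT and a co-registered effusion mask this module computes the
effusion volume (voxel count times voxel volume), extracts masked HU values,
discards those outside the fluid/blood window [0, 80] HU, takes the median,
and applies the clinical decision rules:

* effusion present      — volume strictly greater than 50 mL
* large effusion        — volume strictly greater than 100 mL
* hemopericardium       — filtered median HU strictly greater than 24.5
* alert                 — hemopericardium or large effusion

All thresholds are configurable; the defaults above are the operating points
of the pipeline this package reproduces.  The median is never rounded before
it is compared to the HU cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .imaging_io import CTVolume, SegMask, check_same_grid, voxel_volume_ml


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; all comparisons are strict (>)."""

    volume_ml: float = 50.0
    large_ml: float = 100.0
    hu: float = 24.5
    hu_lo: float = 0.0
    hu_hi: float = 80.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class PEFReport:
    """Per-case output of :func:`classify_case`.

    ``median_hu`` is NaN when no voxel survives the HU filter; the
    hemopericardium flag is then necessarily False.
    """

    case_id: str
    volume_ml: float
    n_voxels: int
    median_hu: float
    n_filtered_out: int
    pef_present: bool
    large_pef: bool
    hemopericardium: bool
    alert: bool
    thresholds_used: Thresholds = field(default_factory=Thresholds)

    @property
    def median_defined(self) -> bool:
        return not math.isnan(self.median_hu)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["median_hu"] = None if math.isnan(self.median_hu) else self.median_hu
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def mask_volume_ml(mask: SegMask) -> float:
    """Mask volume in mL: foreground voxel count times the voxel volume."""
    return mask.n_voxels * voxel_volume_ml(mask.spacing)


def extract_filtered_hu(
    ct: CTVolume,
    mask: SegMask,
    lo: float = DEFAULT_THRESHOLDS.hu_lo,
    hi: float = DEFAULT_THRESHOLDS.hu_hi,
) -> np.ndarray:
    """HU values of mask voxels within the fluid/blood window [lo, hi].

    Bounds are inclusive; values outside are removed because they cannot be
    fluid or blood (air, fat, calcification, metal).
    """
    check_same_grid(ct, mask)
    vals = np.asarray(ct.data)[mask.data.astype(bool)]
    return vals[(vals >= lo) & (vals <= hi)]


def median_hu(values) -> float:
    """Sample median of HU values; NaN for an empty input.

    An even count returns the mean of the two central order statistics.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return math.nan
    return float(np.median(values))


def classify_case(
    ct: CTVolume,
    mask: SegMask,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    case_id: str = "",
) -> PEFReport:
    """Quantify one case and apply the detection/classification rules."""
    check_same_grid(ct, mask)
    volume = mask_volume_ml(mask)
    filtered = extract_filtered_hu(ct, mask, thresholds.hu_lo, thresholds.hu_hi)
    med = median_hu(filtered)
    pef_present = volume > thresholds.volume_ml
    large_pef = volume > thresholds.large_ml
    hemo = (not math.isnan(med)) and med > thresholds.hu
    return PEFReport(
        case_id=case_id,
        volume_ml=volume,
        n_voxels=mask.n_voxels,
        median_hu=med,
        n_filtered_out=mask.n_voxels - filtered.size,
        pef_present=pef_present,
        large_pef=large_pef,
        hemopericardium=hemo,
        alert=hemo or large_pef,
        thresholds_used=thresholds,
    )
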