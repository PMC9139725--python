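"""Synthetic thoracic CT phantoms with ground-truth pericardial effusions.

The phantom is a deliberately simple geometric chest: a soft-tissue body
cylinder containing two lung ellipsoids and an ellipsoidal cardiac blood
pool.  A pericardial effusion is painted as a shell between the heart
surface and an outward-scaled copy of it, with the scale factor solved so
the shell's voxel volume hits a requested target.  Per-case effusion
attenuation is drawn once from the class distribution (hemopericardium vs
simple serous effusion, with separate contrast / non-contrast arms) and
independent Gaussian voxel noise is added on top, so the per-case *median*
HU inside the truth mask recovers the drawn mean almost exactly.

Everything is a deterministic function of the spec's seed, which makes
generated cohorts reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .imaging_io import CTVolume, SegMask, save_mask, save_volume, voxel_volume_ml

# Tissue attenuations (HU)
HU_AIR = -1000.0
HU_BODY = 40.0
HU_LUNG = -800.0
HU_BLOOD = 45.0          # non-enhanced blood pool
HU_BLOOD_CONTRAST = 200.0  # arterial-phase enhanced blood pool
HU_PLEURAL = 10.0        # serous pleural fluid

#: Per-case median-HU distributions (mean, SD) by effusion class and
#: contrast arm, as observed across cases in a clinical cohort.
CLASS_HU_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "hemopericardium": {
        "pooled": (36.10, 9.72),
        "contrast": (36.86, 9.65),
        "noncontrast": (33.99, 10.08),
    },
    "simple_pef": {
        "pooled": (19.20, 5.52),
        "contrast": (20.97, 6.35),
        "noncontrast": (17.59, 4.12),
    },
}
# A physiological rim in a negative case is serous fluid.
CLASS_HU_PARAMS["none"] = CLASS_HU_PARAMS["simple_pef"]

#: Cohort-level effusion-volume model for positive cases: log-normal moment
#: matched to mean 198.20 mL / SD 159.78 mL, truncated to [60, 900] mL.
VOLUME_MEAN_ML = 198.20
VOLUME_SD_ML = 159.78
VOLUME_BOUNDS_ML = (60.0, 900.0)
#: Negatives carry a small physiological rim, well under the 50 mL cutoff.
NEGATIVE_VOLUME_BOUNDS_ML = (10.0, 40.0)
#: Fraction of positive cases acquired with contrast (58/100 in the cohort
#: the generator emulates); negatives are split evenly.
CONTRAST_FRACTION_POSITIVE = 0.58
CONTRAST_FRACTION_NEGATIVE = 0.5
PLEURAL_FRACTION = 0.3

_EFFUSION_CLASSES = ("none", "simple_pef", "hemopericardium")

# Anatomy layout, in mm on a 256 mm reference extent; scaled linearly per
# axis for other grids.  Centres are (x, y, z); semi-axes likewise.
_REF_EXTENT = 256.0
_BODY_CENTER = (128.0, 128.0)
_BODY_SEMI = (115.0, 95.0)
_LUNG_CENTERS = ((66.0, 118.0, 160.0), (190.0, 118.0, 160.0))
_LUNG_SEMI = (40.0, 60.0, 70.0)
_HEART_CENTER = (128.0, 130.0, 160.0)
_HEART_SEMI = (42.0, 38.0, 47.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters that fully determine one phantom."""

    effusion_class: str = "simple_pef"
    target_volume_ml: float | None = None
    contrast: bool = False
    pleural_effusion: bool = False
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd_hu: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effusion_class not in _EFFUSION_CLASSES:
            raise ValueError(
                f"effusion_class must be one of {_EFFUSION_CLASSES}, "
                f"got {self.effusion_class!r}"
            )
        if self.target_volume_ml is not None and self.target_volume_ml < 0:
            raise ValueError("target_volume_ml must be >= 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")

    def resolved_target_volume_ml(self) -> float:
        """Target effusion volume, defaulting by class (25 mL rim for negatives,
        200 mL for positives)."""
        if self.target_volume_ml is not None:
            return float(self.target_volume_ml)
        return 25.0 if self.effusion_class == "none" else 200.0


@dataclass
class TruthRecord:
    """Ground truth carried by one generated phantom."""

    case_id: str
    effusion_class: str
    true_volume_ml: float
    per_case_mean_hu: float
    contrast: bool
    pleural: bool
    seed: int

    def as_row(self) -> dict:
        return asdict(self)


def _ellipsoid_sqnorm(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    """Squared ellipsoid norm field: <=1 inside the ellipsoid."""
    axes = []
    for i in range(3):
        coords = (np.arange(shape[i], dtype=np.float32) + 0.5) * spacing[i]
        axes.append((coords - center_mm[i]) / semi_mm[i])
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    return x * x + y * y + z * z


def _scaled_geometry(shape, spacing):
    """Anatomy positions/sizes scaled from the 256 mm reference extent."""
    extent = tuple(shape[i] * spacing[i] for i in range(3))
    f = tuple(extent[i] / _REF_EXTENT for i in range(3))

    def scale3(v):
        return tuple(v[i] * f[i] for i in range(3))

    geo = {
        "body_center": (_BODY_CENTER[0] * f[0], _BODY_CENTER[1] * f[1]),
        "body_semi": (_BODY_SEMI[0] * f[0], _BODY_SEMI[1] * f[1]),
        "lungs": [(scale3(c), scale3(_LUNG_SEMI)) for c in _LUNG_CENTERS],
        "heart_center": scale3(_HEART_CENTER),
        "heart_semi": scale3(_HEART_SEMI),
    }
    return geo


def expected_lung_volume_ml(
    grid_shape=(128, 128, 128), spacing=(2.0, 2.0, 2.0)
) -> float:
    """Analytic volume of both constructed lung ellipsoids in mL.

    Ignores the small carve-out where the cardiac blood pool overrides lung
    voxels, so treat as an upper reference accurate to a few percent.
    """
    geo = _scaled_geometry(grid_shape, spacing)
    total = 0.0
    for _, semi in geo["lungs"]:
        total += 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2] / 1000.0
    return total


def draw_per_case_mean_hu(
    effusion_class: str, contrast: bool, rng: np.random.Generator
) -> float:
    """Draw the case-level effusion attenuation from the class/arm distribution."""
    arm = "contrast" if contrast else "noncontrast"
    mean, sd = CLASS_HU_PARAMS[effusion_class][arm]
    return float(rng.normal(mean, sd))


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegMask, TruthRecord]:
    """Generate one chest phantom, its truth effusion mask, and its record.

    The effusion shell volume is solved on the voxel grid so the truth-mask
    volume matches the target to within one voxel (far inside the +-5%
    contract).  Raises :class:`GenerationError` when the target volume cannot
    fit between the heart surface and the surrounding anatomy.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing)
    rng = np.random.default_rng(spec.seed)
    geo = _scaled_geometry(shape, spacing)
    vox_ml = voxel_volume_ml(spacing)

    # Body: elliptic cylinder along z.
    xc = (np.arange(shape[0], dtype=np.float32) + 0.5) * spacing[0]
    yc = (np.arange(shape[1], dtype=np.float32) + 0.5) * spacing[1]
    bx = (xc - geo["body_center"][0]) / geo["body_semi"][0]
    by = (yc - geo["body_center"][1]) / geo["body_semi"][1]
    body2d = bx[:, None] ** 2 + by[None, :] ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], shape[2], axis=2)

    lungs = np.zeros(shape, dtype=bool)
    for center, semi in geo["lungs"]:
        lungs |= _ellipsoid_sqnorm(shape, spacing, center, semi) <= 1.0
    lungs &= body

    heart_sq = _ellipsoid_sqnorm(
        shape, spacing, geo["heart_center"], geo["heart_semi"]
    )
    heart = heart_sq <= 1.0
    lungs &= ~heart  # cardiac notch: blood pool overrides lung

    # Effusion shell: voxels outside the heart, inside the body, clear of the
    # lungs, ranked by ellipsoid norm; take the innermost k voxels.
    target_ml = spec.resolved_target_volume_ml()
    k = int(round(target_ml / vox_ml))
    eligible = body & ~lungs & ~heart
    elig_norms = heart_sq[eligible]
    if k > 0:
        if k > elig_norms.size:
            raise GenerationError(
                f"target volume {target_ml:.0f} mL exceeds the "
                f"{elig_norms.size * vox_ml:.0f} mL available around the heart"
            )
        kth = np.partition(elig_norms, k - 1)[k - 1]
        max_sq = _max_shell_sqnorm(geo, shape, spacing)
        if kth > max_sq:
            raise GenerationError(
                f"target volume {target_ml:.0f} mL is geometrically "
                f"unattainable on this grid: shell scale "
                f"{np.sqrt(kth):.2f} exceeds the body clearance limit "
                f"{np.sqrt(max_sq):.2f} along the "
                f"{_limiting_axis(geo)} axis"
            )
        effusion = eligible & (heart_sq <= kth)
    else:
        effusion = np.zeros(shape, dtype=bool)

    per_case_mean_hu = draw_per_case_mean_hu(
        spec.effusion_class, spec.contrast, rng
    )

    pleural = np.zeros(shape, dtype=bool)
    if spec.pleural_effusion:
        # Posterior crescent hugging the right lung, contiguous with but
        # never inside the pericardial shell.
        center, semi = geo["lungs"][1]
        lung_sq = _ellipsoid_sqnorm(shape, spacing, center, semi)
        ymm = (np.arange(shape[1], dtype=np.float32) + 0.5) * spacing[1]
        posterior = np.zeros(shape, dtype=bool)
        posterior[:, ymm > center[1], :] = True
        pleural = (
            (lung_sq > 1.0)
            & (lung_sq <= 1.3)
            & posterior
            & body
            & ~lungs
            & ~heart
            & ~effusion
        )

    hu = np.full(shape, HU_AIR, dtype=np.float32)
    hu[body] = HU_BODY
    hu[lungs] = HU_LUNG
    hu[heart] = HU_BLOOD_CONTRAST if spec.contrast else HU_BLOOD
    hu[pleural] = HU_PLEURAL
    hu[effusion] = per_case_mean_hu
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)
    data = np.rint(hu).astype(np.int16)  # clinical CTs carry integer HU

    ct = CTVolume(data=data, spacing=spacing)
    mask = SegMask(data=effusion.astype(np.uint8), spacing=spacing, label="truth")
    record = TruthRecord(
        case_id=f"phantom_seed{spec.seed}",
        effusion_class=spec.effusion_class,
        true_volume_ml=mask.n_voxels * vox_ml,
        per_case_mean_hu=per_case_mean_hu,
        contrast=spec.contrast,
        pleural=spec.pleural_effusion,
        seed=spec.seed,
    )
    return ct, mask, record


def _max_shell_sqnorm(geo, shape, spacing) -> float:
    """Largest squared shell norm before the scaled heart surface leaves the
    body outline or the grid along some axis."""
    scales = []
    cx, cy, cz = geo["heart_center"]
    ax, ay, az = geo["heart_semi"]
    bx, by = geo["body_center"]
    sx, sy = geo["body_semi"]
    # clearance inside the body ellipse along x and y through the heart centre
    scales.append((bx + sx * np.sqrt(max(0.0, 1 - ((cy - by) / sy) ** 2)) - cx) / ax)
    scales.append((by + sy * np.sqrt(max(0.0, 1 - ((cx - bx) / sx) ** 2)) - cy) / ay)
    extent_z = shape[2] * spacing[2]
    scales.append((extent_z - cz) / az)
    scales.append(cz / az)
    s = min(scales)
    return float(s * s)


def _limiting_axis(geo) -> str:
    # Report which axis bounds the shell most tightly (for error messages).
    cx, cy, cz = geo["heart_center"]
    ax, ay, az = geo["heart_semi"]
    bx, by = geo["body_center"]
    sx, sy = geo["body_semi"]
    sx_clear = (bx + sx - cx) / ax
    sy_clear = (by + sy - cy) / ay
    sz_clear = cz / az
    return ("x", "y", "z")[int(np.argmin([sx_clear, sy_clear, sz_clear]))]


def _draw_positive_volume_ml(rng: np.random.Generator) -> float:
    """Log-normal effusion volume, truncated by rejection."""
    m, s = VOLUME_MEAN_ML, VOLUME_SD_ML
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    lo, hi = VOLUME_BOUNDS_ML
    for _ in range(1000):
        v = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))  # pragma: no cover


def sample_cohort_specs(
    n_hemo: int,
    n_simple: int,
    n_negative: int,
    base_seed: int,
    grid_shape=(128, 128, 128),
    spacing=(2.0, 2.0, 2.0),
    noise_sd_hu: float = 8.0,
) -> list[tuple[str, PhantomSpec]]:
    """Draw per-case parameters for a cohort; returns (case_id, spec) pairs.

    Case order is hemopericardium, then simple effusion, then negatives;
    all random draws come from a single generator seeded with ``base_seed``,
    so the cohort is fully reproducible.
    """
    if min(n_hemo, n_simple, n_negative) < 0:
        raise ValueError("cohort counts must be >= 0")
    rng = np.random.default_rng(base_seed)
    classes = (
        ["hemopericardium"] * n_hemo
        + ["simple_pef"] * n_simple
        + ["none"] * n_negative
    )
    out = []
    for i, cls in enumerate(classes):
        if cls == "none":
            vol = float(rng.uniform(*NEGATIVE_VOLUME_BOUNDS_ML))
            contrast = bool(rng.random() < CONTRAST_FRACTION_NEGATIVE)
        else:
            vol = _draw_positive_volume_ml(rng)
            contrast = bool(rng.random() < CONTRAST_FRACTION_POSITIVE)
        pleural = bool(rng.random() < PLEURAL_FRACTION)
        seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            effusion_class=cls,
            target_volume_ml=vol,
            contrast=contrast,
            pleural_effusion=pleural,
            grid_shape=grid_shape,
            spacing=spacing,
            noise_sd_hu=noise_sd_hu,
            seed=seed,
        )
        out.append((f"case_{i:03d}_{cls}", spec))
    return out


MANIFEST_COLUMNS = [
    "case_id",
    "effusion_class",
    "true_volume_ml",
    "per_case_mean_hu",
    "contrast",
    "pleural",
    "seed",
    "ct_path",
    "mask_path",
]


def generate_cohort(
    n_hemo: int,
    n_simple: int,
    n_negative: int,
    base_seed: int,
    out_dir: str | Path,
    grid_shape=(128, 128, 128),
    spacing=(2.0, 2.0, 2.0),
    noise_sd_hu: float = 8.0,
) -> pd.DataFrame:
    """Generate a cohort to disk: NIfTI pairs plus a ``manifest.csv``.

    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case_id, spec in sample_cohort_specs(
        n_hemo, n_simple, n_negative, base_seed, grid_shape, spacing, noise_sd_hu
    ):
        ct, mask, record = generate_phantom(spec)
        record.case_id = case_id
        ct_path = out_dir / f"{case_id}_ct.nii.gz"
        mask_path = out_dir / f"{case_id}_mask.nii.gz"
        save_volume(ct, ct_path)
        save_mask(mask, mask_path)
        row = record.as_row()
        row["ct_path"] = str(ct_path)
        row["mask_path"] = str(mask_path)
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
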