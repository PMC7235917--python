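"""Digital PET/CT phantoms and synthetic cohorts with known ground truth.

The imaging phantom emulates the posterior lumbar anatomy the quantification
method operates on: an elliptical soft-tissue body (~40 HU) with a
subcutaneous fat layer (~-100 HU), bilateral erector-spinae-like muscle
cylinders (HU within the 0-250 muscle window, true SUV ~1), a central
cortical-bone block (>250 HU, true SUV ~3), and bilateral graft hot regions
of known true SUV adjacent to the bone.  The PET side is the piecewise-
constant truth blurred with an isotropic Gaussian point-spread function and
degraded with seeded mean-proportional Gaussian noise (a pseudo-Poisson
surrogate); an optional rigid misalignment perturbs the PET header geometry
so the metadata-fusion path can be exercised against a known answer.

The cohort generator draws fused/unfused patients with clinical scores
uniform within instrument bounds and summed graft uptake with a configurable
fused-vs-unfused effect, so the statistics layer can be calibrated on nulls
and powered alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CylinderVOI, RigidTransform, rasterize_voi
from .volumes import ImageVolume, Modality, SUVCalibration, decay_corrected_dose

__all__ = [
    "Box",
    "Ellipsoid",
    "PhantomRegion",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "default_phantom_spec",
    "phantom_calibration",
]

AIR_HU = -1000.0
BODY_HU = 40.0
BODY_SUV = 0.5
FAT_HU = -100.0
FAT_SUV = 0.3
MUSCLE_HU = 50.0
MUSCLE_SUV = 1.0
BONE_HU = 700.0
BONE_SUV = 3.0
GRAFT_SUV = 5.0


@dataclass(frozen=True)
class Box:
    """Axis-aligned box: centre and full edge lengths, world mm."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes, world mm."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]


def _rasterize_shape(shape, grid: ImageVolume) -> np.ndarray:
    if isinstance(shape, CylinderVOI):
        return rasterize_voi(shape, grid)
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.index_to_world(idx)
    rel = world - np.asarray(shape.center)
    if isinstance(shape, Box):
        half = np.asarray(shape.size) / 2.0
        inside = np.all(np.abs(rel) <= half + 1e-12, axis=1)
    elif isinstance(shape, Ellipsoid):
        inside = np.einsum("ij,ij->i", rel / shape.radii, rel / shape.radii) <= 1.0 + 1e-12
    else:  # pragma: no cover
        raise TypeError(f"unknown shape {type(shape)}")
    return inside.reshape(grid.shape)


@dataclass(frozen=True)
class PhantomRegion:
    """A homogeneous tissue region: geometry plus its true HU and SUV."""

    name: str
    shape: object  # CylinderVOI | Box | Ellipsoid
    hu: float
    suv: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic PET/CT pair.

    Regions are painted in declaration order with earlier regions taking
    precedence on overlap; the body ellipsoid fills whatever they leave, and
    everything outside it is air.  ``noise_scale`` is the variance of the
    additive Gaussian noise per unit of local mean SUV (0 = noise-free).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body: Ellipsoid = field(default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (80.0, 70.0, 200.0)))
    body_hu: float = BODY_HU
    body_suv: float = BODY_SUV
    regions: list[PhantomRegion] = field(default_factory=list)
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 0.0
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        for reg in self.regions:
            if reg.suv < 0:
                raise ValueError(f"region {reg.name}: true SUV must be >= 0")


@dataclass
class PhantomTruth:
    """Exact per-region ground truth of a generated phantom."""

    regions: dict[str, dict]  # name -> {suv, hu, volume_ml, voxels}
    masks: dict[str, np.ndarray]
    body_mask: np.ndarray

    def as_dict(self) -> dict:
        return {"regions": self.regions}


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Posterior-lumbar phantom: bilateral muscle and graft regions by a bone block.

    The two muscle cylinders are ~20 cm^3 (radius 10 mm, height 63.66 mm)
    mirrored across the mid-sagittal plane; the grafts are bilateral ~4 cm^3
    cylinders at true SUV 5 adjacent to the central bone; a fat sheet lies
    posterior to the muscles.
    """
    muscle_h = 63.662  # pi * 10^2 * 63.662 mm^3 ~= 20 cm^3
    graft_h = 20.372   # pi * 7.9^2 * 20.372 mm^3 ~= 4 cm^3 (radius 7.9)
    regions = [
        PhantomRegion("bone", Box((0.0, 0.0, 0.0), (24.0, 30.0, 110.0)), BONE_HU, BONE_SUV),
        PhantomRegion(
            "graft_L",
            CylinderVOI("graft", "L", 1, (22.0, 0.0, -28.0), (0, 0, 1), 7.9, graft_h),
            BONE_HU, GRAFT_SUV,
        ),
        PhantomRegion(
            "graft_R",
            CylinderVOI("graft", "R", 1, (-22.0, 0.0, -28.0), (0, 0, 1), 7.9, graft_h),
            BONE_HU, GRAFT_SUV,
        ),
        PhantomRegion(
            "muscle_L",
            CylinderVOI("muscle", "L", 1, (34.0, 18.0, 20.0), (0, 0, 1), 10.0, muscle_h),
            MUSCLE_HU, MUSCLE_SUV,
        ),
        PhantomRegion(
            "muscle_R",
            CylinderVOI("muscle", "R", 1, (-34.0, 18.0, 20.0), (0, 0, 1), 10.0, muscle_h),
            MUSCLE_HU, MUSCLE_SUV,
        ),
        PhantomRegion("fat", Box((0.0, 52.0, 0.0), (130.0, 18.0, 160.0)), FAT_HU, FAT_SUV),
    ]
    defaults = dict(regions=regions)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def phantom_calibration(scan_minutes_post_injection: float = 90.0) -> SUVCalibration:
    """Calibration matching the imaging protocol: 2.2 MBq/kg for a 70 kg
    patient (154 MBq) scanned 90 min post injection, 110 min half-life."""
    inj = datetime(2020, 1, 1, 9, 0, 0)
    return SUVCalibration(
        injected_dose_mbq=154.0,
        injection_time=inj,
        scan_time=inj + timedelta(minutes=scan_minutes_post_injection),
        body_weight_kg=70.0,
    )


def generate_phantom(
    spec: PhantomSpec,
    calibration: SUVCalibration | None = None,
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Rasterize a spec into a (PET Bq/mL, CT HU, truth) triple.

    The CT is the noise-free HU map.  The PET is the true SUV map blurred
    with the spec's Gaussian PSF, degraded with seeded mean-proportional
    Gaussian noise, converted to activity concentration with ``calibration``
    (default: the 154 MBq / 70 kg / 90 min protocol), and optionally carrying
    a misaligned header geometry.
    """
    cal = calibration or phantom_calibration()
    shape = spec.grid_shape
    spacing = spec.spacing_mm
    # grid centred on the world origin
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    grid = ImageVolume(np.zeros(shape), spacing, origin, np.eye(3), Modality.PET_SUV)

    hu = np.full(shape, AIR_HU)
    suv = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    truth_regions: dict[str, dict] = {}
    for reg in spec.regions:
        inside = _rasterize_shape(reg.shape, grid) & ~assigned
        masks[reg.name] = inside
        hu[inside] = reg.hu
        suv[inside] = reg.suv
        assigned |= inside
        vol_ml = float(inside.sum()) * grid.voxel_volume_ml
        truth_regions[reg.name] = {
            "suv": reg.suv, "hu": reg.hu,
            "volume_ml": vol_ml, "voxels": int(inside.sum()),
        }
    body_mask = _rasterize_shape(spec.body, grid)
    rest = body_mask & ~assigned
    hu[rest] = spec.body_hu
    suv[rest] = spec.body_suv

    # PET: blur, noise, convert SUV -> Bq/mL
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(spacing)
        pet_suv = ndimage.gaussian_filter(suv, sigma=sigma_vox, mode="constant")
    else:
        pet_suv = suv.copy()
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        std = np.sqrt(spec.noise_scale * np.clip(pet_suv, 0.0, None))
        pet_suv = pet_suv + rng.normal(size=shape) * std
    scale_bqml_per_suv = decay_corrected_dose(cal, cal.scan_time) * 1e6 / (cal.body_weight_kg * 1000.0)
    pet_bqml = pet_suv * scale_bqml_per_suv

    pet = ImageVolume(pet_bqml, spacing, origin, np.eye(3), Modality.PET_BQML)
    if not spec.misalignment.is_identity():
        H = spec.misalignment.homogeneous @ pet.affine
        M = H[:3, :3]
        sp = np.linalg.norm(M, axis=0)
        pet = ImageVolume(pet_bqml, tuple(sp), tuple(H[:3, 3]), M / sp, Modality.PET_BQML)
    ct = ImageVolume(hu, spacing, origin, np.eye(3), Modality.CT_HU)
    return pet, ct, PhantomTruth(truth_regions, masks, body_mask)


# -- synthetic cohorts -----------------------------------------------------

# instrument bounds: (low, high)
SCORE_BOUNDS = {
    "WLK_D": (0.0, 1000.0),
    "VAS_B": (0.0, 10.0),
    "VAS_L": (0.0, 10.0),
    "TAN": (0.0, 30.0),
    "ODI": (0.0, 100.0),
    "EQ_5D": (0.0, 1.0),
}

# observed-range defaults: baseline uniform range and 12-month-change uniform range
SCORE_RANGES = {
    "WLK_D": ((15.0, 1000.0), (0.0, 985.0)),
    "VAS_B": ((0.0, 9.6), (-8.5, 0.1)),
    "VAS_L": ((1.1, 9.3), (-9.1, 0.8)),
    "TAN": ((0.0, 30.0), (0.0, 10.0)),
    "ODI": ((16.0, 62.0), (-54.0, -4.0)),
    "EQ_5D": ((0.32, 0.82), (0.0, 0.67)),
}


@dataclass
class CohortSpec:
    """Synthetic cohort description.

    ``uptake_effect`` shifts the fused group's summed SUVtotal relative to
    the unfused mean (0 = null).  Score draws are independent uniforms within
    the observed ranges, truncated to instrument bounds.
    """

    n: int = 18
    fusion_prob: float = 4.0 / 18.0
    uptake_mean: float = 1224.0
    uptake_sd: float = 330.0
    uptake_effect: float = -46.0
    score_ranges: dict = field(default_factory=lambda: dict(SCORE_RANGES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion_prob <= 1.0:
            raise ValueError("fusion_prob must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a reproducible patient table.

    One row per patient with id, graft-material group, fused flag, age, BMI,
    baseline (``*_bs``) and 12-month (``*_12m``) clinical scores, and summed
    suv_total / c_suv_total.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    fused = rng.random(n) < spec.fusion_prob
    group = rng.choice(["allograft", "iFactor"], size=n, p=[10 / 18, 8 / 18])
    rows: dict[str, np.ndarray] = {
        "id": np.array([f"P{i + 1:03d}" for i in range(n)]),
        "group": group,
        "fused": fused,
        "age": rng.uniform(60.0, 78.0, n),
        "bmi": rng.uniform(21.8, 35.0, n),
    }
    for var, (bs_range, delta_range) in spec.score_ranges.items():
        lo, hi = SCORE_BOUNDS[var]
        bs = rng.uniform(*bs_range, n)
        delta = rng.uniform(*delta_range, n)
        rows[f"{var}_bs"] = np.clip(bs, lo, hi)
        rows[f"{var}_12m"] = np.clip(bs + delta, lo, hi)
    uptake = rng.normal(spec.uptake_mean, spec.uptake_sd, n)
    uptake = uptake + np.where(fused, spec.uptake_effect, 0.0)
    uptake = np.clip(uptake, 50.0, None)
    rows["suv_total"] = uptake
    rows["c_suv_total"] = uptake * rng.uniform(1.0, 1.15, n)
    return pd.DataFrame(rows)
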