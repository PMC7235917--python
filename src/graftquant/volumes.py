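"""Volumetric image container, NIfTI/DICOM I/O and SUV calibration.

The internal data model is a single :class:`ImageVolume`: a 3-D scalar grid
plus an affine voxel-to-world mapping (LPS millimetres, 0-based indices,
values located at voxel centres) and a modality tag.  NIfTI-1 is the
canonical on-disk format; DICOM series reading is a convenience layer that
converts into the same model.

PET images are expected in activity concentration (Bq/mL), already corrected
for attenuation, scatter, randoms and dead-time.  :func:`to_suv` converts to
body-weight standardized uptake values using the injected dose decay-corrected
to scan start (18F half-life 110 min) and a 1 g/mL tissue density.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "ImageVolume",
    "SUVCalibration",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "decay_corrected_dose",
    "to_suv",
]

F18_HALF_LIFE_MIN = 110.0


class Modality(str, enum.Enum):
    """Units carried by the voxel grid."""

    CT_HU = "CT_HU"
    PET_BQML = "PET_BQML"
    PET_SUV = "PET_SUV"


class ModalityError(ValueError):
    """An operation received a volume of the wrong modality."""


class GeometryError(ValueError):
    """Inconsistent or missing grid geometry."""


# physically plausible CT range used for sanity checking, HU
_CT_HU_RANGE = (-1024.0, 4000.0)


@dataclass
class ImageVolume:
    """A 3-D image with world geometry.

    Parameters
    ----------
    voxels
        3-D array of scalar values in the modality's units.
    spacing
        Per-axis voxel edge length in mm, strictly positive.
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    orientation
        3x3 orthonormal direction matrix (world-from-index directions,
        columns are the world directions of the i, j, k axes).
    modality
        One of :class:`Modality`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: Modality = Modality.PET_SUV

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)
        R = self.orientation
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise GeometryError("orientation must be a 3x3 orthonormal matrix")
        self.modality = Modality(self.modality)
        if self.modality is Modality.CT_HU:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < _CT_HU_RANGE[0] - 1e-6 or hi > _CT_HU_RANGE[1] + 1e-6:
                raise ValueError(
                    f"CT HU outside plausible range {_CT_HU_RANGE}: [{lo}, {hi}]"
                )

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mm^3 == 1e-3 mL)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index-to-world affine (mm)."""
        A = np.eye(4)
        A[:3, :3] = self.orientation * np.asarray(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        index = np.asarray(index, dtype=np.float64)
        M = self.orientation * np.asarray(self.spacing)
        return index @ M.T + np.asarray(self.origin)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to fractional voxel indices."""
        world = np.asarray(world, dtype=np.float64)
        M = self.orientation * np.asarray(self.spacing)
        return (world - np.asarray(self.origin)) @ np.linalg.inv(M).T

    def world_center(self) -> np.ndarray:
        """World position of the geometric centre of the grid."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(c)

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        """Same geometry, new voxel data (and optionally modality)."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64),
                       modality=self.modality if modality is None else modality)


@dataclass(frozen=True)
class SUVCalibration:
    """Injected-dose calibration for body-weight SUV.

    injected_dose is the activity (MBq) at ``injection_time``; body_weight in
    kg; half_life in minutes (default: 18F, 110 min).
    """

    injected_dose_mbq: float
    injection_time: datetime
    scan_time: datetime
    body_weight_kg: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected_dose_mbq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be > 0")
        if self.scan_time < self.injection_time:
            raise ValueError("scan_time must not precede injection_time")


def decay_corrected_dose(cal: SUVCalibration, at_time: datetime) -> float:
    """Injected dose (MBq) decayed to ``at_time``.

    Returns ``injected_dose * 2**(-dt/half_life)`` with dt in minutes.
    """
    dt_min = (at_time - cal.injection_time).total_seconds() / 60.0
    if dt_min < 0:
        raise ValueError("at_time precedes injection_time")
    return cal.injected_dose_mbq * 2.0 ** (-dt_min / cal.half_life_min)


def to_suv(pet: ImageVolume, cal: SUVCalibration) -> ImageVolume:
    """Convert a PET activity-concentration image (Bq/mL) to body-weight SUV.

    SUV(v) = C(v) / (decayed dose [Bq] / body weight [g]); tissue density is
    taken as 1 g/mL so SUV is dimensionless.  The dose is decay-corrected to
    scan start.  Geometry is unchanged.
    """
    if pet.modality is not Modality.PET_BQML:
        raise ModalityError(f"to_suv expects PET_BQML, got {pet.modality}")
    dose_bq = decay_corrected_dose(cal, cal.scan_time) * 1e6
    weight_g = cal.body_weight_kg * 1000.0
    suv = pet.voxels / (dose_bq / weight_g)
    return pet.with_voxels(suv, modality=Modality.PET_SUV)


# -- I/O -------------------------------------------------------------------

def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; modality recorded in the header description."""
    img = nib.Nifti1Image(vol.voxels, vol.affine)
    img.header["descrip"] = vol.modality.value.encode()
    nib.save(img, str(path))


def _decompose_affine(affine: np.ndarray):
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("degenerate affine: zero-length axis")
    orientation = M / spacing
    origin = affine[:3, 3]
    return tuple(spacing), tuple(origin), orientation


def read_volume(path: str | Path, modality: Modality | str) -> ImageVolume:
    """Read a NIfTI volume (or a DICOM series directory) as an ImageVolume.

    ``modality`` declares the voxel units; if the file carries a modality tag
    that conflicts with the declaration, a ValueError is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    modality = Modality(modality)
    if path.is_dir():
        return read_dicom_series(path, modality)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"expected 3-D data, got shape {data.shape}")
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="ignore")
    if descrip in Modality._value2member_map_ and descrip != modality.value:
        raise ValueError(
            f"declared modality {modality.value} conflicts with header tag {descrip}"
        )
    spacing, origin, orientation = _decompose_affine(img.affine)
    return ImageVolume(data, spacing, origin, orientation, modality)


def read_dicom_series(directory: str | Path, modality: Modality | str) -> ImageVolume:
    """Read a DICOM series directory via SimpleITK (optional dependency)."""
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("DICOM series reading requires SimpleITK") from exc
    modality = Modality(modality)
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise GeometryError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    image = reader.Execute()
    # sitk arrays are (z, y, x); transpose to (x, y, z) index order
    data = sitk.GetArrayFromImage(image).transpose(2, 1, 0).astype(np.float64)
    spacing = image.GetSpacing()
    origin = image.GetOrigin()
    orientation = np.asarray(image.GetDirection()).reshape(3, 3)
    return ImageVolume(data, spacing, origin, orientation, modality)
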