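"""Cylindrical VOIs, rigid transforms and PET/CT fusion resampling.

VOIs are analytic cylinders in world space (LPS mm) that can be rasterized
onto any grid with a centre-inside rule, and mirrored across the mid-sagittal
plane so the right-side reference region keeps the dimensions of the left.

Rigid transforms use intrinsic z-y-x Euler angles in degrees about an
explicit rotation centre.  Fusion starts from scan metadata (header
geometry) and may be refined by a manual adjustment supplied in the run
config; PET is then resampled onto the CT grid, which is the geometry
reference for HU masking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, Modality

__all__ = [
    "CylinderVOI",
    "RigidTransform",
    "rasterize_voi",
    "mirror_voi",
    "fuse_from_metadata",
    "refine_rigid",
    "resample_to_grid",
]

_SIDE_SWAP = {"L": "R", "R": "L"}


@dataclass(frozen=True)
class CylinderVOI:
    """An analytic cylinder VOI.

    label is one of muscle/graft, side 'L'/'R', with a fusion-level index;
    centre in world mm; axis a unit vector; radius and height in mm.
    """

    label: str            # "muscle" or "graft"
    side: str             # "L" or "R"
    level: int
    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.label not in ("muscle", "graft"):
            raise ValueError(f"label must be muscle|graft, got {self.label!r}")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be L|R, got {self.side!r}")
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("radius and height must be positive")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be nonzero")
        object.__setattr__(self, "axis", tuple(a / n))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def name(self) -> str:
        return f"{self.label}_{self.side}_L{self.level}"

    @property
    def analytic_volume_ml(self) -> float:
        """pi r^2 h in mL."""
        return float(np.pi * self.radius_mm**2 * self.height_mm) / 1000.0


def rasterize_voi(voi: CylinderVOI, grid: ImageVolume) -> np.ndarray:
    """Binary mask of grid voxels whose centres lie inside the cylinder.

    Returns an all-False mask (no error) when the VOI misses the grid
    entirely; the caller decides whether that is a problem.
    """
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.index_to_world(idx)
    rel = world - np.asarray(voi.center)
    axis = np.asarray(voi.axis)
    axial = rel @ axis
    radial2 = np.einsum("ij,ij->i", rel, rel) - axial**2
    inside = (np.abs(axial) <= voi.height_mm / 2.0) & (
        radial2 <= voi.radius_mm**2 + 1e-12
    )
    return inside.reshape(grid.shape)


def mirror_voi(voi: CylinderVOI, sagittal_plane_x: float) -> CylinderVOI:
    """Reflect a VOI across the plane x = sagittal_plane_x, swapping its side.

    Radius and height are preserved, so the mirrored reference VOI keeps the
    dimensions of its contralateral counterpart.
    """
    cx, cy, cz = voi.center
    ax, ay, az = voi.axis
    return replace(
        voi,
        side=_SIDE_SWAP[voi.side],
        center=(2.0 * sagittal_plane_x - cx, cy, cz),
        axis=(-ax, ay, az),
    )


def _euler_zyx_matrix(rz: float, ry: float, rx: float) -> np.ndarray:
    """Intrinsic z-y-x rotation matrix, angles in degrees."""
    cz, sz = np.cos(np.radians(rz)), np.sin(np.radians(rz))
    cy, sy = np.cos(np.radians(ry)), np.sin(np.radians(ry))
    cx, sx = np.cos(np.radians(rx)), np.sin(np.radians(rx))
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """Rigid world-space transform: rotate about ``center`` then translate.

    ``p' = R (p - c) + c + t`` with R the intrinsic z-y-x Euler rotation
    (degrees) and t the translation in mm.
    """

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (rz, ry, rx)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        """Build from a rotation matrix and translation, centre at origin."""
        # intrinsic z-y-x Euler extraction
        ry = np.degrees(np.arcsin(np.clip(-R[2, 0], -1.0, 1.0)))
        if abs(R[2, 0]) < 1.0 - 1e-12:
            rz = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
            rx = np.degrees(np.arctan2(R[2, 1], R[2, 2]))
        else:  # gimbal lock
            rz = np.degrees(np.arctan2(-R[0, 1], R[1, 1]))
            rx = 0.0
        return cls((rz, ry, rx), tuple(np.asarray(t, dtype=float)))

    @property
    def matrix(self) -> np.ndarray:
        """Rotation matrix R."""
        rz, ry, rx = self.rotations_deg
        return _euler_zyx_matrix(rz, ry, rx)

    @property
    def homogeneous(self) -> np.ndarray:
        """4x4 matrix form."""
        R = self.matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        H = np.eye(4)
        H[:3, :3] = R
        H[:3, 3] = c + t - R @ c
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform world points of shape (..., 3)."""
        points = np.asarray(points, dtype=float)
        R = self.matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (points - c) @ R.T + c + t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        H = self.homogeneous @ other.homogeneous
        return RigidTransform.from_matrix(H[:3, :3], H[:3, 3])

    def inverse(self) -> "RigidTransform":
        H = np.linalg.inv(self.homogeneous)
        return RigidTransform.from_matrix(H[:3, :3], H[:3, 3])

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.homogeneous, np.eye(4), atol=tol))


def fuse_from_metadata(pet: ImageVolume, ct: ImageVolume) -> RigidTransform:
    """Rigid transform mapping PET world space onto CT world space from headers.

    Scanners acquiring both modalities in one session share a frame of
    reference; the header-implied transform is then the identity.  When the
    headers disagree (e.g. a phantom pair written with a known misalignment of
    the PET geometry), the two grids are assumed to image the same anatomy
    over congruent extents, and the transform aligns the PET orientation and
    grid centre onto the CT's: ``p' = (O_ct O_pet^-1)(p - c_pet) + c_ct``.
    """
    same_orientation = np.allclose(pet.orientation, ct.orientation, atol=1e-9)
    c_pet = pet.world_center()
    c_ct = ct.world_center()
    if same_orientation and np.allclose(c_pet, c_ct, atol=1e-9):
        return RigidTransform.identity()
    R = ct.orientation @ pet.orientation.T
    t = c_ct - R @ c_pet
    return RigidTransform.from_matrix(R, t)


def refine_rigid(initial: RigidTransform, adjustment: RigidTransform) -> RigidTransform:
    """Compose a manual adjustment (applied after) onto the metadata transform."""
    return adjustment.compose(initial)


def resample_to_grid(
    moving: ImageVolume,
    transform: RigidTransform,
    reference: ImageVolume,
    interpolation: str = "trilinear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Express ``moving`` on the ``reference`` grid.

    ``transform`` maps moving world space onto reference world space; each
    reference voxel centre is pulled back through its inverse and interpolated
    in the moving image ('nearest' or 'trilinear').  Out-of-field voxels get
    ``fill_value`` (default: -1000 HU for CT, 0 otherwise).
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill_value is None:
        fill_value = -1000.0 if moving.modality is Modality.CT_HU else 0.0
    order = 0 if interpolation == "nearest" else 1

    idx = np.indices(reference.shape).reshape(3, -1).T
    world_ref = reference.index_to_world(idx)
    world_mov = transform.inverse().apply(world_ref)
    idx_mov = moving.world_to_index(world_mov)
    out = ndimage.map_coordinates(
        moving.voxels,
        idx_mov.T,
        order=order,
        mode="constant",
        cval=fill_value,
    ).reshape(reference.shape)
    return ImageVolume(
        out,
        reference.spacing,
        reference.origin,
        reference.orientation,
        moving.modality,
    )
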