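"""Core uptake quantification: HU masking, SUVpeak thresholding, PVC.

The method quantifies bone-graft NaF uptake against a patient-specific
background reference:

1. the paraspinal-muscle VOI is restricted by a fixed CT window of 0-250 HU
   (excluding bone and fat),
2. SUVpeak (mean SUV over the hottest 1 cm^3 sphere) of the muscle reference
   sets a fixed lower threshold,
3. each graft VOI is segmented at that threshold; connected components
   smaller than 1 cm^3 are discarded as noise,
4. total uptake SUVtotal = SUVmean x segmented volume (SUV.mL), and a
   partial-volume-corrected cSUVtotal is obtained by a local-background
   spill-out correction using a Gaussian point-spread model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, Modality

__all__ = [
    "HUWindow",
    "SegmentationResult",
    "hu_mask",
    "suv_peak",
    "graft_threshold",
    "threshold_segment",
    "estimate_local_background",
    "delineation_threshold",
    "pvc_correct",
    "patient_graft_uptake",
    "InsufficientVolumeError",
]

MUSCLE_HU_WINDOW = (0.0, 250.0)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InsufficientVolumeError(ValueError):
    """Mask too small for the requested peak sphere."""


class EmptyMaskWarning(UserWarning):
    pass


@dataclass(frozen=True)
class HUWindow:
    """Inclusive CT attenuation window [lo, hi] in HU."""

    lo: float = MUSCLE_HU_WINDOW[0]
    hi: float = MUSCLE_HU_WINDOW[1]

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")


@dataclass
class SegmentationResult:
    """Binary segmentation plus the uptake metric set.

    Volumes in mL; suv_total and c_suv_total in SUV.mL.  c_suv_total is
    populated by :func:`pvc_correct`; until then it equals suv_total.
    """

    mask: np.ndarray
    components: list[tuple[int, float]] = field(default_factory=list)
    volume_ml: float = 0.0
    suv_mean: float = 0.0
    suv_max: float = 0.0
    suv_peak: float = float("nan")
    suv_total: float = 0.0
    c_suv_total: float = 0.0
    threshold_used: float = float("nan")
    pvc_fallback: bool = False


def hu_mask(ct_on_grid: ImageVolume, voi_mask: np.ndarray, window: HUWindow) -> np.ndarray:
    """Restrict a VOI mask to voxels within the HU window (inclusive).

    Used with the default 0-250 HU window this keeps muscle while excluding
    bone (>250 HU) and fat (<0 HU).  An empty result is returned with a
    warning, not an error.
    """
    if ct_on_grid.modality is not Modality.CT_HU:
        raise ValueError(f"hu_mask expects CT_HU, got {ct_on_grid.modality}")
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if voi_mask.shape != ct_on_grid.shape:
        raise ValueError("voi_mask shape does not match the CT grid")
    hu = ct_on_grid.voxels
    out = voi_mask & (hu >= window.lo) & (hu <= window.hi)
    if not out.any():
        warnings.warn("HU-windowed mask is empty", EmptyMaskWarning, stacklevel=2)
    return out


def _sphere_offsets(spacing: tuple[float, float, float], volume_ml: float) -> np.ndarray:
    """Integer index offsets whose voxel centres lie in a sphere of the given volume."""
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sp = np.asarray(spacing)
    half = np.ceil(radius_mm / sp).astype(int)
    rng = [np.arange(-h, h + 1) for h in half]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    dist2 = np.einsum("ij,ij->i", grid * sp, grid * sp)
    return grid[dist2 <= radius_mm**2 + 1e-9]


def suv_peak(
    suv: ImageVolume,
    mask: np.ndarray,
    sphere_volume_ml: float = 1.0,
    min_coverage: float = 0.5,
) -> float:
    """SUVpeak: maximal mean SUV over a sphere of ``sphere_volume_ml``.

    Sphere centres are restricted to voxel centres inside the mask; each
    sphere is clipped to the mask and must retain at least ``min_coverage``
    of its voxels.  Ties break to the lowest linear (C-order) index, making
    the result deterministic.
    """
    if suv.modality is not Modality.PET_SUV:
        raise ValueError(f"suv_peak expects PET_SUV, got {suv.modality}")
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask * suv.voxel_volume_ml < sphere_volume_ml:
        raise InsufficientVolumeError(
            f"mask volume {n_mask * suv.voxel_volume_ml:.3f} mL < "
            f"sphere volume {sphere_volume_ml} mL"
        )
    offsets = _sphere_offsets(suv.spacing, sphere_volume_ml)
    min_count = int(np.ceil(min_coverage * len(offsets)))

    centers = np.argwhere(mask)  # C-order => rows sorted by linear index
    shape = np.asarray(suv.shape)
    vox = suv.voxels
    best = -np.inf
    for c in centers:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        sel = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        n = int(sel.sum())
        if n < min_count:
            continue
        m = float(vox[pts[sel, 0], pts[sel, 1], pts[sel, 2]].mean())
        if m > best:  # strict: first (lowest-index) centre wins ties
            best = m
    if not np.isfinite(best):
        raise InsufficientVolumeError(
            "no sphere placement reaches the required mask coverage"
        )
    return best


def graft_threshold(
    left_peak: float | None,
    right_peak: float | None,
    rule: str = "mean",
) -> float | tuple[float, float]:
    """Combine the two muscle SUVpeaks into the fixed lower graft threshold.

    rule='mean' (default) averages left and right; 'max' takes the larger;
    'per-side' returns (left, right) so each graft VOI uses its own side.
    """
    if rule not in ("mean", "max", "per-side"):
        raise ValueError(f"unknown threshold rule {rule!r}")
    if rule == "per-side":
        if left_peak is None or right_peak is None:
            raise ValueError("per-side rule requires both muscle SUVpeaks")
        return (float(left_peak), float(right_peak))
    sides = [p for p in (left_peak, right_peak) if p is not None]
    if not sides:
        raise ValueError("at least one muscle SUVpeak is required")
    return float(np.mean(sides)) if rule == "mean" else float(np.max(sides))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def threshold_segment(
    suv: ImageVolume,
    voi_mask: np.ndarray,
    lower_threshold: float,
    min_component_ml: float = 1.0,
    connectivity: int = 26,
    strict_min: bool = False,
) -> SegmentationResult:
    """Fixed-lower-threshold segmentation with small-component rejection.

    Voxels are kept iff inside ``voi_mask`` and SUV >= ``lower_threshold``
    (inclusive).  Connected components (26-neighbourhood by default) smaller
    than ``min_component_ml`` are removed, excluding single high-uptake voxels
    and small separated voxel groups.  An empty post-filter mask yields a
    valid zero-volume result, not an error.
    """
    if suv.modality is not Modality.PET_SUV:
        raise ValueError(f"threshold_segment expects PET_SUV, got {suv.modality}")
    if lower_threshold <= 0:
        raise ValueError("lower_threshold must be > 0")
    voi_mask = np.asarray(voi_mask, dtype=bool)
    raw = voi_mask & (suv.voxels >= lower_threshold)
    vvol = suv.voxel_volume_ml

    labels, n_labels = ndimage.label(raw, structure=_connectivity_structure(connectivity))
    keep = np.zeros_like(raw)
    components: list[tuple[int, float]] = []
    if n_labels:
        counts = np.bincount(labels.ravel())[1:]  # component sizes, label order
        for lab, cnt in enumerate(counts, start=1):
            vol = cnt * vvol
            retained = vol > min_component_ml if strict_min else vol >= min_component_ml
            if retained:
                keep |= labels == lab
                components.append((lab, float(vol)))

    res = SegmentationResult(mask=keep, components=components,
                             threshold_used=float(lower_threshold))
    n = int(keep.sum())
    res.volume_ml = n * vvol
    if n:
        vals = suv.voxels[keep]
        res.suv_mean = float(vals.mean())
        res.suv_max = float(vals.max())
        res.suv_total = res.suv_mean * res.volume_ml
        res.c_suv_total = res.suv_total
        if res.volume_ml >= 1.0:
            try:
                res.suv_peak = suv_peak(suv, keep, sphere_volume_ml=1.0)
            except InsufficientVolumeError:
                # a >=1 mL mask can still be too thin for any 50%-covered sphere
                res.suv_peak = float("nan")
    return res


def _background_shell(mask: np.ndarray, spacing: np.ndarray,
                      margin_mm: float, thickness_mm: float,
                      exclude_mask: np.ndarray | None) -> np.ndarray:
    it_margin = max(1, int(round(margin_mm / float(spacing.min()))))
    it_outer = it_margin + max(1, int(round(thickness_mm / float(spacing.min()))))
    struct = ndimage.generate_binary_structure(3, 1)
    inner = ndimage.binary_dilation(mask, struct, iterations=it_margin)
    outer = ndimage.binary_dilation(mask, struct, iterations=it_outer)
    shell = outer & ~inner
    if exclude_mask is not None:
        shell &= ~np.asarray(exclude_mask, dtype=bool)
    return shell


def estimate_local_background(
    suv: ImageVolume,
    mask: np.ndarray,
    margin_mm: float,
    thickness_mm: float | None = None,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Median SUV in a shell around ``mask``.

    The shell starts ``margin_mm`` outside the mask (to stay clear of
    spill-out) and is ``thickness_mm`` thick (default: equal to the margin).
    """
    mask = np.asarray(mask, dtype=bool)
    shell = _background_shell(mask, np.asarray(suv.spacing), margin_mm,
                              thickness_mm if thickness_mm is not None else margin_mm,
                              exclude_mask)
    if not shell.any():
        raise ValueError("background shell is empty")
    return float(np.median(suv.voxels[shell]))


def delineation_threshold(suv_max: float, background: float,
                          fraction: float = 0.4) -> float:
    """Background-corrected fractional-of-maximum delineation threshold.

    ``background + fraction * (suv_max - background)``; with a Gaussian PSF
    a fraction near 0.4 recovers the true boundary of a uniform hot object
    on a uniform background.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    return background + fraction * (suv_max - background)


def pvc_correct(
    seg: SegmentationResult,
    suv: ImageVolume,
    psf_fwhm_mm: float,
    shell_margin_mm: float | None = None,
    shell_thickness_mm: float | None = None,
    exclude_mask: np.ndarray | None = None,
    r_floor: float = 0.05,
) -> float:
    """Partial-volume-corrected total uptake (cSUVtotal), in SUV.mL.

    Local-background spill correction: the background SUV ``B`` is estimated
    from a shell around the segmented mask (offset by ``shell_margin_mm`` to
    stay clear of spill-out, default one FWHM; thickness default one FWHM;
    other segmented voxels excluded via ``exclude_mask``).  The in-mask
    retention ``r`` is the mean, over the mask, of the mask indicator
    convolved with the Gaussian PSF.  The corrected mean is

        (observed mean - B (1 - r)) / r

    clipped from below to the observed mean (the correction models spill-out
    of a hot region into a colder background; when the estimate would reduce
    the mean, the uncorrected value is kept).  If ``r`` falls below
    ``r_floor`` the correction is unstable: the uncorrected suv_total is
    returned and ``seg.pvc_fallback`` is set.

    Updates ``seg.c_suv_total`` in place and returns it.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    mask = np.asarray(seg.mask, dtype=bool)
    if not mask.any():
        seg.c_suv_total = 0.0
        return 0.0
    if psf_fwhm_mm == 0.0:
        seg.c_suv_total = seg.suv_total
        return seg.c_suv_total

    spacing = np.asarray(suv.spacing)
    sigma_vox = (psf_fwhm_mm * FWHM_TO_SIGMA) / spacing
    r = float(ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma_vox)[mask].mean())
    if r < r_floor:
        warnings.warn(
            f"PVC retention r={r:.3f} below floor {r_floor}; "
            "returning uncorrected suv_total",
            UserWarning,
            stacklevel=2,
        )
        seg.pvc_fallback = True
        seg.c_suv_total = seg.suv_total
        return seg.c_suv_total

    margin = psf_fwhm_mm if shell_margin_mm is None else shell_margin_mm
    thickness = psf_fwhm_mm if shell_thickness_mm is None else shell_thickness_mm
    try:
        background = estimate_local_background(suv, mask, margin, thickness,
                                               exclude_mask)
    except ValueError:
        warnings.warn("empty background shell; returning uncorrected suv_total",
                      UserWarning, stacklevel=2)
        seg.pvc_fallback = True
        seg.c_suv_total = seg.suv_total
        return seg.c_suv_total
    corrected_mean = (seg.suv_mean - background * (1.0 - r)) / r
    corrected_mean = max(corrected_mean, seg.suv_mean)
    seg.c_suv_total = corrected_mean * seg.volume_ml
    return seg.c_suv_total


def patient_graft_uptake(segs: list[SegmentationResult]) -> tuple[float, float]:
    """Sum graft uptake across all insertion levels and both sides.

    Returns the per-patient (suv_total, c_suv_total) in SUV.mL.
    """
    if not segs:
        raise ValueError("at least one segmentation result is required")
    return (
        float(sum(s.suv_total for s in segs)),
        float(sum(s.c_suv_total for s in segs)),
    )
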