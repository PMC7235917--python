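"""Shared fixtures: small grids, calibrations and brute-force oracles.

The oracles here are deliberately naive (pure-Python loops, exhaustive
enumeration) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import math
from collections import deque
from datetime import datetime, timedelta

import numpy as np
import pytest

from graftquant import ImageVolume, Modality, SUVCalibration


@pytest.fixture
def calibration() -> SUVCalibration:
    """154 MBq (2.2 MBq/kg x 70 kg) injected, scanned 90 min later."""
    inj = datetime(2020, 1, 1, 9, 0, 0)
    return SUVCalibration(
        injected_dose_mbq=154.0,
        injection_time=inj,
        scan_time=inj + timedelta(minutes=90),
        body_weight_kg=70.0,
    )


def make_suv_volume(voxels, spacing=(2.0, 2.0, 2.0), origin=None) -> ImageVolume:
    voxels = np.asarray(voxels, dtype=float)
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(voxels.shape, spacing))
    return ImageVolume(voxels, spacing, origin, np.eye(3), Modality.PET_SUV)


def make_ct_volume(voxels, spacing=(2.0, 2.0, 2.0), origin=None) -> ImageVolume:
    voxels = np.asarray(voxels, dtype=float)
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(voxels.shape, spacing))
    return ImageVolume(voxels, spacing, origin, np.eye(3), Modality.CT_HU)


# -- independent oracles ---------------------------------------------------

def brute_force_suv_peak(vox, mask, spacing, sphere_volume_ml=1.0, min_coverage=0.5):
    """Exhaustive SUVpeak: pure-Python loop over every in-mask centre.

    Returns (best mean, best centre) with ties broken by lowest linear index.
    """
    radius = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sx, sy, sz = spacing
    hx = int(math.ceil(radius / sx))
    hy = int(math.ceil(radius / sy))
    hz = int(math.ceil(radius / sz))
    offsets = []
    for i in range(-hx, hx + 1):
        for j in range(-hy, hy + 1):
            for k in range(-hz, hz + 1):
                if (i * sx) ** 2 + (j * sy) ** 2 + (k * sz) ** 2 <= radius**2 + 1e-9:
                    offsets.append((i, j, k))
    min_count = math.ceil(min_coverage * len(offsets))
    nx, ny, nz = mask.shape
    best, best_center = None, None
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                vals = []
                for i, j, k in offsets:
                    a, b, c = x + i, y + j, z + k
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and mask[a, b, c]:
                        vals.append(float(vox[a, b, c]))
                if len(vals) < min_count:
                    continue
                m = math.fsum(vals) / len(vals)
                if best is None or m > best:
                    best, best_center = m, (x, y, z)
    return best, best_center


def brute_force_components(mask, connectivity=26):
    """Flood-fill connected components; returns list of frozensets of voxels."""
    if connectivity == 26:
        neigh = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                 for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    nx, ny, nz = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                comp = set()
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    comp.add((cx, cy, cz))
                    for i, j, k in neigh:
                        a, b, c = cx + i, cy + j, cz + k
                        if (0 <= a < nx and 0 <= b < ny and 0 <= c < nz
                                and mask[a, b, c] and not seen[a, b, c]):
                            seen[a, b, c] = True
                            queue.append((a, b, c))
                comps.append(frozenset(comp))
    return comps


def brute_force_threshold_segment(vox, voi_mask, threshold, voxel_volume_ml,
                                  min_component_ml=1.0, connectivity=26):
    """Oracle for threshold segmentation: retained voxel set after filtering."""
    raw = voi_mask & (vox >= threshold)
    retained = set()
    for comp in brute_force_components(raw, connectivity):
        if len(comp) * voxel_volume_ml >= min_component_ml:
            retained |= comp
    return retained
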