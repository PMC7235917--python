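"""Config-driven end-to-end pipeline.

Per patient: fuse PET to CT from headers (plus any manual rigid adjustment
from the config), resample the SUV image onto the CT grid, HU-window the
muscle reference VOIs, take their SUVpeak as the fixed graft threshold,
segment every graft VOI with the minimum-component filter, apply partial
volume correction, and sum uptake over all levels and both sides.  Outputs
are a per-patient metrics CSV row, NIfTI label maps of the graft
segmentation, and a JSON provenance sidecar echoing every parameter used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify
from .cohort_stats import run_cohort_stats, StatReport
from .geometry import CylinderVOI, RigidTransform, fuse_from_metadata, mirror_voi, \
    rasterize_voi, refine_rigid, resample_to_grid
from .quantify import HUWindow, graft_threshold, hu_mask, patient_graft_uptake, \
    pvc_correct, suv_peak, threshold_segment
from .volumes import ImageVolume, Modality, SUVCalibration, read_volume, to_suv, write_volume

log = logging.getLogger("graftquant")

__all__ = ["MethodParams", "PatientConfig", "RunConfig", "run_patient", "run_cohort"]


@dataclass(frozen=True)
class MethodParams:
    """All tunable method parameters, echoed verbatim into provenance."""

    hu_window: tuple[float, float] = (0.0, 250.0)
    sphere_volume_ml: float = 1.0
    min_component_ml: float = 1.0
    threshold_rule: str = "mean"       # mean | max | per-side
    pvc_fwhm_mm: float = 6.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        HUWindow(*self.hu_window)  # validates lo < hi
        if self.sphere_volume_ml <= 0 or self.min_component_ml < 0:
            raise ValueError("sphere_volume_ml > 0 and min_component_ml >= 0 required")
        if self.threshold_rule not in ("mean", "max", "per-side"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.pvc_fwhm_mm < 0:
            raise ValueError("pvc_fwhm_mm must be >= 0")


@dataclass
class PatientConfig:
    id: str
    pet_path: Path
    ct_path: Path
    calibration: SUVCalibration
    vois: list[CylinderVOI]
    adjustment: RigidTransform = field(default_factory=RigidTransform.identity)
    fused_label: bool | None = None  # HRCT adjudication, input only


@dataclass
class RunConfig:
    patients: list[PatientConfig]
    method: MethodParams = field(default_factory=MethodParams)
    cohort_csv: Path | None = None
    output_dir: Path = Path("results")
    seed: int = 0


def _parse_voi(d: dict) -> CylinderVOI:
    return CylinderVOI(
        label=d["label"], side=d["side"], level=int(d.get("level", 1)),
        center=tuple(d["center"]), axis=tuple(d.get("axis", (0, 0, 1))),
        radius_mm=float(d["radius_mm"]), height_mm=float(d["height_mm"]),
    )


def _parse_transform(d: dict | None) -> RigidTransform:
    if not d:
        return RigidTransform.identity()
    return RigidTransform(
        rotations_deg=tuple(d.get("rotations_deg", (0, 0, 0))),
        translation_mm=tuple(d.get("translation_mm", (0, 0, 0))),
        center_mm=tuple(d.get("center_mm", (0, 0, 0))),
    )


def _parse_calibration(d: dict) -> SUVCalibration:
    return SUVCalibration(
        injected_dose_mbq=float(d["injected_dose_mbq"]),
        injection_time=datetime.fromisoformat(str(d["injection_time"])),
        scan_time=datetime.fromisoformat(str(d["scan_time"])),
        body_weight_kg=float(d["body_weight_kg"]),
        half_life_min=float(d.get("half_life_min", 110.0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, expanding mirrored VOIs and validating paths."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    method = MethodParams(**{k: tuple(v) if k == "hu_window" else v
                             for k, v in (raw.get("method") or {}).items()})
    patients = []
    for p in raw["patients"]:
        vois = [_parse_voi(v) for v in p["vois"]]
        plane_x = p.get("sagittal_plane_x")
        if p.get("mirror_vois") and plane_x is not None:
            vois += [mirror_voi(v, float(plane_x)) for v in list(vois)]
        pet_path = base / p["pet"]
        ct_path = base / p["ct"]
        for fp in (pet_path, ct_path):
            if not fp.exists():
                raise FileNotFoundError(fp)
        patients.append(PatientConfig(
            id=str(p["id"]), pet_path=pet_path, ct_path=ct_path,
            calibration=_parse_calibration(p["calibration"]),
            vois=vois, adjustment=_parse_transform(p.get("adjustment")),
            fused_label=p.get("fused"),
        ))
    cohort_csv = raw.get("cohort_csv")
    return RunConfig(
        patients=patients, method=method,
        cohort_csv=base / cohort_csv if cohort_csv else None,
        output_dir=Path(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )


def quantify_patient(
    pet: ImageVolume,
    ct: ImageVolume,
    calibration: SUVCalibration,
    vois: list[CylinderVOI],
    method: MethodParams = MethodParams(),
    adjustment: RigidTransform | None = None,
):
    """Run the whole quantification for one patient on in-memory volumes.

    Returns (metrics dict, {voi name: SegmentationResult}, suv-on-CT-grid).
    """
    suv = to_suv(pet, calibration)
    transform = fuse_from_metadata(suv, ct)
    if adjustment is not None and not adjustment.is_identity():
        transform = refine_rigid(transform, adjustment)
    suv_on_ct = resample_to_grid(suv, transform, ct, interpolation="trilinear")

    window = HUWindow(*method.hu_window)
    muscle_vois = [v for v in vois if v.label == "muscle"]
    graft_vois = [v for v in vois if v.label == "graft"]
    if not muscle_vois or not graft_vois:
        raise ValueError("need at least one muscle and one graft VOI")

    peaks: dict[str, float] = {}
    for side in ("L", "R"):
        side_vois = [v for v in muscle_vois if v.side == side]
        if not side_vois:
            continue
        mask = np.zeros(ct.shape, dtype=bool)
        for v in side_vois:
            mask |= rasterize_voi(v, ct)
        mask = hu_mask(ct, mask, window)
        peaks[side] = suv_peak(suv_on_ct, mask,
                               sphere_volume_ml=method.sphere_volume_ml)
    thr = graft_threshold(peaks.get("L"), peaks.get("R"), rule=method.threshold_rule)

    segs: dict[str, quantify.SegmentationResult] = {}
    all_masks = [rasterize_voi(v, ct) for v in graft_vois]
    for v, vmask in zip(graft_vois, all_masks):
        t = thr if not isinstance(thr, tuple) else thr[0 if v.side == "L" else 1]
        seg = threshold_segment(
            suv_on_ct, vmask, t,
            min_component_ml=method.min_component_ml,
            connectivity=method.connectivity,
        )
        segs[v.name] = seg
    # PVC per graft VOI; other grafts' voxels excluded from the background shell
    union = np.zeros(ct.shape, dtype=bool)
    for seg in segs.values():
        union |= seg.mask
    for seg in segs.values():
        pvc_correct(seg, suv_on_ct, method.pvc_fwhm_mm,
                    exclude_mask=union & ~seg.mask)

    suv_total, c_suv_total = patient_graft_uptake(list(segs.values()))
    metrics = {
        "muscle_suv_peak_L": peaks.get("L"),
        "muscle_suv_peak_R": peaks.get("R"),
        "graft_threshold": thr if not isinstance(thr, tuple) else list(thr),
        "suv_total": suv_total,
        "c_suv_total": c_suv_total,
        "per_voi": {
            name: {
                "volume_ml": s.volume_ml, "suv_mean": s.suv_mean,
                "suv_max": s.suv_max, "suv_peak": s.suv_peak,
                "suv_total": s.suv_total, "c_suv_total": s.c_suv_total,
                "threshold_used": s.threshold_used,
                "pvc_fallback": s.pvc_fallback,
            } for name, s in segs.items()
        },
    }
    return metrics, segs, suv_on_ct


def run_patient(patient: PatientConfig, method: MethodParams,
                output_dir: Path) -> dict:
    """Load one patient's images, quantify, and write outputs + provenance.

    Any stage error marks the patient failed in the returned row; the caller
    continues with the remaining patients.
    """
    t0 = time.perf_counter()
    out = Path(output_dir) / patient.id
    out.mkdir(parents=True, exist_ok=True)
    row: dict = {"id": patient.id, "status": "ok", "reason": ""}
    if patient.fused_label is not None:
        row["fused"] = bool(patient.fused_label)
    try:
        pet = read_volume(patient.pet_path, Modality.PET_BQML)
        ct = read_volume(patient.ct_path, Modality.CT_HU)
        metrics, segs, _ = quantify_patient(
            pet, ct, patient.calibration, patient.vois,
            method=method, adjustment=patient.adjustment,
        )
        label_map = np.zeros(ct.shape)
        for i, (name, seg) in enumerate(sorted(segs.items()), start=1):
            label_map[seg.mask] = i
        write_volume(ImageVolume(label_map, ct.spacing, ct.origin,
                                 ct.orientation, Modality.PET_SUV),
                     out / "graft_labels.nii.gz")
        row.update({k: v for k, v in metrics.items() if k != "per_voi"})
        provenance = {
            "patient": patient.id,
            "method": asdict(method),
            "adjustment": asdict(patient.adjustment),
            "metrics": metrics,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
    except Exception as exc:  # noqa: BLE001 - pipeline isolates patient failures
        log.warning("patient %s failed: %s", patient.id, exc)
        row["status"] = "failed"
        row["reason"] = f"{type(exc).__name__}: {exc}"
    log.info("patient %s done in %.2fs (%s)", patient.id,
             time.perf_counter() - t0, row["status"])
    return row


def run_cohort(config: RunConfig) -> tuple[pd.DataFrame, StatReport | None]:
    """Run every patient, merge with the clinical table, run the statistics.

    Returns the per-patient metrics table and the StatReport (None when the
    merged table cannot support any test, e.g. a single fusion class).
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    rows = [run_patient(p, config.method, config.output_dir)
            for p in config.patients]
    metrics = pd.DataFrame(rows)
    metrics.to_csv(config.output_dir / "patient_metrics.csv", index=False)

    table = metrics[metrics["status"] == "ok"].copy() if len(metrics) else metrics
    if config.cohort_csv is not None:
        # the clinical table defines the cohort; imaging-derived uptake
        # overrides its columns for the patients that were quantified
        clinical = pd.read_csv(config.cohort_csv)
        if len(table):
            img = table[["id", "suv_total", "c_suv_total"]]
            merged = clinical.merge(img, on="id", how="left", suffixes=("", "_img"))
            for col in ("suv_total", "c_suv_total"):
                if f"{col}_img" in merged:
                    merged[col] = merged[f"{col}_img"].fillna(
                        merged[col] if col in clinical else np.nan)
                    merged = merged.drop(columns=[f"{col}_img"])
            table = merged
        else:
            table = clinical
    if not len(table):
        raise ValueError("no usable records for cohort statistics")
    report = None
    if "fused" in table and table["fused"].astype(bool).nunique() == 2:
        report = run_cohort_stats(table)
        report.descriptives.to_csv(config.output_dir / "stat_report.csv")
        (config.output_dir / "stat_report.txt").write_text(report.to_text())
    else:
        log.warning("fusion outcome has a single class; logistic tests skipped")
    return metrics, report
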