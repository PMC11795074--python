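"""End-to-end cardiac motion estimation workflow.

Mirrors the clinical processing chain: register the end-diastolic CT to the
end-systolic CT, evaluate registration quality inside the myocardium-union
ROI, partition the LV into the AHA 17 segments, apply the displacement field
to the contour points of the CTV, the segments and the ICD lead tip, and
summarise motion and concordance in CSV tables and bull's-eye maps.

Everything is deterministic for fixed inputs: the run manifest records
parameter values, package versions and input hashes (no timestamps), so a
rerun produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aha17 import AHALabelMap, partition_aha17, segment_point_sets
from .concordance import (
    MotionSeries,
    RoiMetrics,
    build_evaluation_roi,
    evaluate_registration,
    motion_euclidean_distance,
    pcc,
    wilcoxon_signed_rank,
)
from .core import Landmarks, StructurePointSet, VolumeImage
from .motion import (
    MotionSummary,
    motion_table,
    select_inferior_tip,
    summarize_structure,
)
from .registration import (
    DisplacementField,
    RegistrationParams,
    invert_field,
    register,
    warp_volume,
)

logger = logging.getLogger("cardiomotion")

__all__ = [
    "PipelineConfig",
    "CaseResult",
    "run_case",
    "run_pipeline",
    "tip_ctv_concordance",
    "tip_segment_distances",
]

_CSV_FLOAT_FORMAT = "%.6f"
_DIRECTIONS = ("rl", "ap", "si", "3d")


@dataclass
class PipelineConfig:
    """File-based configuration of one pipeline run."""

    ed_volume: Path
    es_volume: Path
    myo_mask: Path
    cavity_mask: Path
    structures: Path
    landmarks: Path
    output_dir: Path
    params: RegistrationParams = dc_field(default_factory=RegistrationParams)
    log_level: str = "INFO"
    make_maps: bool = True

    @classmethod
    def from_json(cls, path: Path | str) -> "PipelineConfig":
        path = Path(path)
        payload = json.loads(path.read_text())
        base = path.parent

        def resolve(key: str) -> Path:
            p = Path(payload[key])
            return p if p.is_absolute() else base / p

        params = RegistrationParams(**payload.get("params", {}))
        return cls(
            ed_volume=resolve("ed_volume"),
            es_volume=resolve("es_volume"),
            myo_mask=resolve("myo_mask"),
            cavity_mask=resolve("cavity_mask"),
            structures=resolve("structures"),
            landmarks=resolve("landmarks"),
            output_dir=resolve("output_dir"),
            params=params,
            log_level=payload.get("log_level", "INFO"),
            make_maps=payload.get("make_maps", True),
        )

    def validate(self) -> None:
        for key in ("ed_volume", "es_volume", "myo_mask", "cavity_mask", "structures", "landmarks"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")


@dataclass
class CaseResult:
    """In-memory products of one pipeline run."""

    field: DisplacementField
    inverse_field: DisplacementField
    displaced_ed: VolumeImage
    roi_metrics: RoiMetrics
    labelmap: AHALabelMap
    summaries: list[MotionSummary]
    motion: pd.DataFrame

    def summary(self, name: str) -> MotionSummary:
        for s in self.summaries:
            if s.name == name:
                return s
        raise KeyError(name)


def _stage(name: str, start: float) -> None:
    logger.info("%s done in %.1f s", name, time.perf_counter() - start)


def run_case(
    ed: VolumeImage,
    es: VolumeImage,
    myo_mask: np.ndarray,
    cavity_mask: np.ndarray,
    structures: list[StructurePointSet],
    landmarks: Landmarks,
    params: RegistrationParams | None = None,
) -> CaseResult:
    """Run the full motion estimation chain on in-memory inputs.

    ``structures`` supplies the CTV(s) and ICD lead tip(s); LV segments are
    derived from the masks.  With several tips, only the most inferior one
    is analysed.
    """
    params = params or RegistrationParams()

    t0 = time.perf_counter()
    motion_field = register(ed, es, params)
    _stage("registration", t0)

    t0 = time.perf_counter()
    inverse = invert_field(motion_field)
    displaced_ed = warp_volume(ed, inverse)
    roi = build_evaluation_roi(np.asarray(myo_mask, dtype=bool), motion_field)
    metrics = evaluate_registration(es, ed, displaced_ed, roi)
    _stage("registration quality", t0)

    t0 = time.perf_counter()
    labelmap = partition_aha17(myo_mask, cavity_mask, landmarks, ed.spacing, ed.origin)
    segments = segment_point_sets(labelmap)
    _stage("AHA 17-segment partition", t0)

    t0 = time.perf_counter()
    ctvs = sorted((s for s in structures if s.role == "CTV"), key=lambda s: s.name)
    tips = [s for s in structures if s.role == "ICD_tip"]
    analysed: list[StructurePointSet] = list(ctvs)
    if tips:
        analysed.append(select_inferior_tip(tips))
    analysed.extend(segments)
    summaries = [summarize_structure(motion_field, s) for s in analysed]
    table = motion_table(summaries)
    _stage("motion summaries", t0)

    return CaseResult(
        field=motion_field,
        inverse_field=inverse,
        displaced_ed=displaced_ed,
        roi_metrics=metrics,
        labelmap=labelmap,
        summaries=summaries,
        motion=table,
    )


# -- concordance across structures/cases -------------------------------------


def _series(summaries: list[MotionSummary], direction: str) -> np.ndarray:
    if direction == "3d":
        return np.array([s.com.magnitude_3d for s in summaries])
    return np.array([getattr(s.com, direction) for s in summaries])


def tip_segment_distances(result: CaseResult) -> pd.DataFrame:
    """Per-segment distance between ICD tip motion and segment motion (one case).

    Signed CoM components per direction; magnitudes in 3D.
    """
    tip = [s for s in result.summaries if s.role == "ICD_tip"]
    if not tip:
        raise ValueError("case has no ICD tip structure")
    tip_s = tip[0]
    rows = []
    for s in result.summaries:
        if s.role != "LV_segment":
            continue
        segment = int(s.name.split("_")[1])
        rows.append(
            {
                "segment": segment,
                "structure": s.name,
                "dist_rl_mm": abs(s.com.rl - tip_s.com.rl),
                "dist_ap_mm": abs(s.com.ap - tip_s.com.ap),
                "dist_si_mm": abs(s.com.si - tip_s.com.si),
                "dist_3d_mm": abs(s.com.magnitude_3d - tip_s.com.magnitude_3d),
            }
        )
    return pd.DataFrame(rows).sort_values("segment").reset_index(drop=True)


def tip_ctv_concordance(
    case_tables: list[pd.DataFrame], labels: list[str] | None = None
) -> pd.DataFrame:
    """Concordance of ICD tip motion vs CTV motion across cases.

    Each table is one case's motion table.  Cases contribute one pair per
    CTV (a patient with two CTVs contributes two pairs, both against that
    patient's tip).  Per direction: Pearson r and p, Wilcoxon signed-rank p,
    Euclidean distance.  Signed components for RL/AP/SI, magnitudes for 3D.
    """
    pairs: dict[str, tuple[list[float], list[float]]] = {
        d: ([], []) for d in _DIRECTIONS
    }
    pair_labels: list[str] = []
    for i, table in enumerate(case_tables):
        tips = table[table["role"] == "ICD_tip"]
        ctvs = table[table["role"] == "CTV"]
        if tips.empty or ctvs.empty:
            raise ValueError(f"case {i}: needs both an ICD tip and a CTV row")
        tip = tips.iloc[0]
        for _, ctv in ctvs.iterrows():
            label = labels[i] if labels else f"case{i}"
            pair_labels.append(f"{label}:{ctv['structure']}")
            for d in _DIRECTIONS:
                col = "com_3d_mm" if d == "3d" else f"com_{d}_mm"
                pairs[d][0].append(float(tip[col]))
                pairs[d][1].append(float(ctv[col]))

    rows = []
    for d in _DIRECTIONS:
        tip_series = MotionSeries(pair_labels, pairs[d][0])
        ctv_series = MotionSeries(pair_labels, pairs[d][1])
        try:
            r, p = pcc(tip_series, ctv_series)
        except ValueError:  # constant series across cases
            r, p = float("nan"), float("nan")
        try:
            _, wp = wilcoxon_signed_rank(tip_series, ctv_series)
        except ValueError:
            wp = float("nan")
        rows.append(
            {
                "direction": d,
                "n": len(pair_labels),
                "pearson_r": r,
                "pearson_p": round(p, 3),
                "wilcoxon_p": round(wp, 3) if np.isfinite(wp) else wp,
                "euclidean_mm": motion_euclidean_distance(tip_series, ctv_series),
                "series_convention": "signed CoM components" if d != "3d" else "3D magnitudes",
            }
        )
    return pd.DataFrame(rows)


# -- file-based run -----------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _ctv_segments(result: CaseResult, structures: list[StructurePointSet]) -> tuple[int, ...]:
    """Segments overlapped by any CTV (for bull's-eye annotation)."""
    grid = VolumeImage(
        np.zeros(result.labelmap.labels.shape, np.float32),
        result.labelmap.spacing,
        result.labelmap.origin,
    )
    segs: set[int] = set()
    for s in structures:
        if s.role != "CTV":
            continue
        idx = np.rint(grid.world_to_voxel(s.points)).astype(int)
        idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
        labels = result.labelmap.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        segs.update(int(v) for v in np.unique(labels) if v > 0)
    return tuple(sorted(segs))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the workflow from files and write the report bundle.

    Returns a name -> path mapping of the written outputs.
    """
    from . import io as cmio
    from .report import bullseye_map

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ed = cmio.read_volume(config.ed_volume)
    es = cmio.read_volume(config.es_volume)
    myo = cmio.read_volume(config.myo_mask).intensities > 0.5
    cavity = cmio.read_volume(config.cavity_mask).intensities > 0.5
    structures = cmio.read_point_sets(config.structures)
    landmarks = cmio.read_landmarks(config.landmarks)

    result = run_case(ed, es, myo, cavity, structures, landmarks, config.params)

    outputs: dict[str, Path] = {}
    outputs["field"] = cmio.write_field(result.field, out / "field.nii.gz")
    labelmap_vol = VolumeImage(
        result.labelmap.labels.astype(np.int16), result.labelmap.spacing, result.labelmap.origin
    )
    outputs["labelmap"] = cmio.write_volume(labelmap_vol, out / "aha17_labels.nii.gz")
    outputs["motion"] = out / "motion.csv"
    result.motion.to_csv(outputs["motion"], index=False, float_format=_CSV_FLOAT_FORMAT)
    outputs["roi_metrics"] = out / "roi_metrics.csv"
    result.roi_metrics.to_frame().to_csv(
        outputs["roi_metrics"], index=False, float_format=_CSV_FLOAT_FORMAT
    )

    has_tip = any(s.role == "ICD_tip" for s in result.summaries)
    if has_tip:
        outputs["tip_segment_distances"] = out / "tip_segment_distances.csv"
        tip_segment_distances(result).to_csv(
            outputs["tip_segment_distances"], index=False, float_format=_CSV_FLOAT_FORMAT
        )

    if config.make_maps:
        seg_rows = result.motion[result.motion["role"] == "LV_segment"]
        values = seg_rows.sort_values("structure")["com_3d_mm"].to_numpy()
        outputs["bullseye_com3d"] = out / "bullseye_com3d.png"
        bullseye_map(
            values,
            outputs["bullseye_com3d"],
            title="CoM motion, 3D (mm)",
            ctv_segments=_ctv_segments(result, structures),
            colorbar_label="mm",
        )

    manifest = {
        "package": {"name": "cardiomotion", "version": __version__},
        "params": {
            "pyramid_levels": config.params.pyramid_levels,
            "iterations_per_level": list(config.params.iterations_per_level),
            "update_smoothing_sigma": config.params.update_smoothing_sigma,
            "field_smoothing_sigma": config.params.field_smoothing_sigma,
            "convergence_tolerance": config.params.convergence_tolerance,
        },
        "inputs": {
            key: {"file": Path(getattr(config, key)).name, "sha256": _sha256(getattr(config, key))}
            for key in ("ed_volume", "es_volume", "myo_mask", "cavity_mask", "structures", "landmarks")
        },
        "conventions": {
            "axes": "x=RL, y=AP, z=SI (z increases superior)",
            "field": "ED -> ES motion field on the ED grid, voxel units",
            "com": "unweighted mean of structure points",
            "tip_selection": "most inferior tip CoM along SI; ties by name",
            "wilcoxon_zero_method": "drop",
            "euclidean": "per-direction on signed CoM components, 3D on magnitudes; not normalised by case count",
        },
        "outputs": sorted(p.name for p in outputs.values()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs
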