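"""AHA 17-segment partition of an LV myocardium mask.

The left-ventricular myocardium is divided into the standard American Heart
Association segments: 6 basal (1-6), 6 mid-cavity (7-12), 4 apical (13-16)
and the apical cap (17), from three landmarks only (epicardial apex, base
center, anterior RV insertion point).

Geometry
--------
* The long-axis coordinate ``t`` runs from 0 at the base center to 1 at the
  apex, by orthogonal projection onto the base->apex axis.
* The apical cap (segment 17) is the myocardium distal to the apical extent
  of the blood-pool cavity; the remaining extent is split into equal
  basal/mid/apical thirds.
* The circumferential angle ``theta`` is measured about the long axis,
  starting at the RV-insertion direction and increasing from anterior toward
  the septum, so that the 60-degree sectors fall in AHA order
  (anterior, anteroseptal, inferoseptal, inferior, inferolateral,
  anterolateral).  Apical sectors span 90 degrees, offset by 45 degrees so
  that segment 13 (apical anterior) straddles the RV-insertion direction.

The angular conventions are recorded in the label map metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridMismatchError, Landmarks, StructurePointSet, VolumeImage

__all__ = ["AHALabelMap", "SEGMENT_NAMES", "partition_aha17", "segment_point_sets"]

SEGMENT_NAMES: dict[int, str] = {
    1: "basal_anterior",
    2: "basal_anteroseptal",
    3: "basal_inferoseptal",
    4: "basal_inferior",
    5: "basal_inferolateral",
    6: "basal_anterolateral",
    7: "mid_anterior",
    8: "mid_anteroseptal",
    9: "mid_inferoseptal",
    10: "mid_inferior",
    11: "mid_inferolateral",
    12: "mid_anterolateral",
    13: "apical_anterior",
    14: "apical_septal",
    15: "apical_inferior",
    16: "apical_lateral",
    17: "apex",
}


@dataclass
class AHALabelMap:
    """Integer grid: 0 = non-myocardium, 1-17 = AHA segment IDs."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        bad = set(np.unique(self.labels)) - set(range(18))
        if bad:
            raise ValueError(f"labels outside 0..17: {sorted(bad)}")

    def segment_mask(self, segment: int) -> np.ndarray:
        if not 1 <= segment <= 17:
            raise ValueError(f"segment must be 1..17, got {segment}")
        return self.labels == segment

    def segment_counts(self) -> dict[int, int]:
        return {s: int((self.labels == s).sum()) for s in range(1, 18)}


def _angular_frame(landmarks: Landmarks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(e_ref, e_perp, axis): e_ref points toward the RV insertion."""
    axis = landmarks.long_axis
    d = landmarks.rv_insertion - landmarks.base_center
    e_ref = d - (d @ axis) * axis
    e_ref /= np.linalg.norm(e_ref)
    e_perp = np.cross(axis, e_ref)
    return e_ref, e_perp, axis


def partition_aha17(
    myo_mask: np.ndarray,
    cavity_mask: np.ndarray,
    landmarks: Landmarks,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> AHALabelMap:
    """Assign every myocardium voxel an AHA segment label 1-17.

    ``cavity_mask`` is the LV blood pool, used only to locate the apical
    extent of the cavity (the segment-17 boundary).
    """
    myo_mask = np.asarray(myo_mask, dtype=bool)
    cavity_mask = np.asarray(cavity_mask, dtype=bool)
    if myo_mask.shape != cavity_mask.shape:
        raise GridMismatchError(
            f"mask shapes differ: {myo_mask.shape} vs {cavity_mask.shape}"
        )
    if not myo_mask.any():
        raise ValueError("myocardium mask is empty")
    if not cavity_mask.any():
        raise ValueError("cavity mask is empty")

    grid = VolumeImage(np.zeros(myo_mask.shape, dtype=np.float32), spacing, origin)
    e_ref, e_perp, axis = _angular_frame(landmarks)
    length = landmarks.long_axis_length

    def t_of(points: np.ndarray) -> np.ndarray:
        return ((points - landmarks.base_center) @ axis) / length

    cavity_points = grid.voxel_to_world(np.argwhere(cavity_mask))
    t_cap = float(t_of(cavity_points).max())

    myo_idx = np.argwhere(myo_mask)
    points = grid.voxel_to_world(myo_idx)
    t = np.clip(t_of(points), 0.0, None)
    d = points - landmarks.base_center
    theta = np.degrees(np.arctan2(d @ e_perp, d @ e_ref)) % 360.0

    third = t_cap / 3.0
    labels_flat = np.empty(len(myo_idx), dtype=np.int16)
    sector6 = np.minimum((theta // 60.0).astype(int), 5)
    sector4 = np.minimum((((theta + 45.0) % 360.0) // 90.0).astype(int), 3)
    basal = t < third
    mid = (t >= third) & (t < 2 * third)
    apical = (t >= 2 * third) & (t <= t_cap)
    cap = t > t_cap
    labels_flat[basal] = 1 + sector6[basal]
    labels_flat[mid] = 7 + sector6[mid]
    labels_flat[apical] = 13 + sector4[apical]
    labels_flat[cap] = 17

    labels = np.zeros(myo_mask.shape, dtype=np.int16)
    labels[myo_idx[:, 0], myo_idx[:, 1], myo_idx[:, 2]] = labels_flat
    metadata = {
        "t_cap": t_cap,
        "third_extent_mm": third * length,
        "angular_zero": "rv_insertion direction",
        "angular_direction": "anterior -> anteroseptal (cross(axis, e_ref))",
        "long_axis_mm": [float(x) for x in axis],
        "base_center_mm": [float(x) for x in landmarks.base_center],
    }
    return AHALabelMap(labels, tuple(spacing), tuple(origin), metadata)


def segment_point_sets(labelmap: AHALabelMap) -> list[StructurePointSet]:
    """Per-segment mm point clouds (voxel centers), in segment order 1..17.

    Raises if any segment is empty (a well-formed LV mask populates all 17).
    """
    grid = VolumeImage(
        np.zeros(labelmap.labels.shape, dtype=np.float32), labelmap.spacing, labelmap.origin
    )
    out = []
    for seg in range(1, 18):
        idx = np.argwhere(labelmap.labels == seg)
        if idx.size == 0:
            raise ValueError(f"segment {seg} ({SEGMENT_NAMES[seg]}) is empty")
        out.append(
            StructurePointSet(
                f"AHA_{seg:02d}_{SEGMENT_NAMES[seg]}",
                grid.voxel_to_world(idx),
                role="LV_segment",
            )
        )
    return out
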