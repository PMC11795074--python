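"""Structure motion from a displacement field.

The field estimated by the registration module is sampled at the contour
points of each structure (CTV, AHA segments, ICD lead tip), giving per-point
motion vectors in mm along the patient axes (RL, AP, SI) and in 3D.  Both the
center-of-mass (CoM) motion and per-point motion statistics are reported,
since non-rigid contraction makes CoM motion alone an incomplete summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import StructurePointSet
from .registration import DisplacementField

__all__ = [
    "MotionRecord",
    "MotionSummary",
    "ClampError",
    "sample_field_at_points",
    "displace_points",
    "com_motion",
    "pointwise_motion",
    "summarize_structure",
    "motion_table",
    "select_inferior_tip",
]

#: a run fails when more than this fraction of points falls outside the grid
MAX_CLAMPED_FRACTION = 0.01


class ClampError(ValueError):
    """Too many structure points fell outside the displacement-field grid."""


@dataclass(frozen=True)
class MotionRecord:
    """Signed RL/AP/SI motion components and 3D magnitude, in mm."""

    rl: float
    ap: float
    si: float
    magnitude_3d: float

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MotionRecord":
        v = np.asarray(v, dtype=float).reshape(3)
        return cls(float(v[0]), float(v[1]), float(v[2]), float(np.linalg.norm(v)))

    def as_vector(self) -> np.ndarray:
        return np.array([self.rl, self.ap, self.si])


@dataclass
class MotionSummary:
    """CoM motion plus per-point motion statistics for one structure."""

    name: str
    role: str
    n_points: int
    n_clamped: int
    com: MotionRecord
    pointwise: dict[str, dict[str, float]] = field(default_factory=dict)


def sample_field_at_points(
    field: DisplacementField, points: np.ndarray
) -> tuple[np.ndarray, int]:
    """Trilinearly sample the field at mm points; returns (vectors_mm, n_clamped).

    Points outside the grid are clamped to the edge (``mode='nearest'``) and
    counted.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("empty point list")
    spacing = np.asarray(field.spacing)
    origin = np.asarray(field.origin)
    voxel = (points - origin) / spacing
    upper = np.asarray(field.grid_shape) - 1
    n_clamped = int(np.any((voxel < 0) | (voxel > upper), axis=1).sum())
    coords = voxel.T
    vectors_vox = np.column_stack(
        [
            ndimage.map_coordinates(field.vectors[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ]
    )
    return vectors_vox * spacing, n_clamped


def displace_points(field: DisplacementField, points: np.ndarray) -> tuple[np.ndarray, int]:
    """Apply the field to mm points: returns (points + u(points) in mm, n_clamped)."""
    vectors, n_clamped = sample_field_at_points(field, points)
    return np.atleast_2d(np.asarray(points, dtype=float)) + vectors, n_clamped


def com_motion(points: np.ndarray, displaced_points: np.ndarray) -> MotionRecord:
    """CoM(displaced) - CoM(original) per axis, with 3D magnitude."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    displaced_points = np.atleast_2d(np.asarray(displaced_points, dtype=float))
    if points.shape != displaced_points.shape:
        raise ValueError(
            f"point sets differ in shape: {points.shape} vs {displaced_points.shape}"
        )
    return MotionRecord.from_vector(displaced_points.mean(axis=0) - points.mean(axis=0))


def _stats(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(values.mean()),
        "sd": sd,
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def pointwise_motion(
    points: np.ndarray, displaced_points: np.ndarray
) -> dict[str, dict[str, float]]:
    """Statistics of per-point |RL|, |AP|, |SI| and 3D motion magnitudes."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    displaced_points = np.atleast_2d(np.asarray(displaced_points, dtype=float))
    if points.shape != displaced_points.shape:
        raise ValueError(
            f"point sets differ in shape: {points.shape} vs {displaced_points.shape}"
        )
    d = displaced_points - points
    return {
        "rl_abs": _stats(np.abs(d[:, 0])),
        "ap_abs": _stats(np.abs(d[:, 1])),
        "si_abs": _stats(np.abs(d[:, 2])),
        "mag_3d": _stats(np.linalg.norm(d, axis=1)),
    }


def summarize_structure(
    field: DisplacementField,
    structure: StructurePointSet,
    max_clamped_fraction: float = MAX_CLAMPED_FRACTION,
) -> MotionSummary:
    """Motion summary of one structure under the field.

    Raises :class:`ClampError` when more than ``max_clamped_fraction`` of the
    points lie outside the field grid.
    """
    displaced, n_clamped = displace_points(field, structure.points)
    if n_clamped > max_clamped_fraction * structure.n_points:
        raise ClampError(
            f"{structure.name}: {n_clamped}/{structure.n_points} points outside the "
            f"field grid (limit {max_clamped_fraction:.0%})"
        )
    return MotionSummary(
        name=structure.name,
        role=structure.role,
        n_points=structure.n_points,
        n_clamped=n_clamped,
        com=com_motion(structure.points, displaced),
        pointwise=pointwise_motion(structure.points, displaced),
    )


def motion_table(summaries: list[MotionSummary]) -> pd.DataFrame:
    """Flat per-structure motion table (one row per structure)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "structure": s.name,
            "role": s.role,
            "n_points": s.n_points,
            "n_clamped": s.n_clamped,
            "com_rl_mm": s.com.rl,
            "com_ap_mm": s.com.ap,
            "com_si_mm": s.com.si,
            "com_3d_mm": s.com.magnitude_3d,
        }
        for metric, stats in s.pointwise.items():
            for stat, value in stats.items():
                row[f"{metric}_{stat}_mm"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def select_inferior_tip(tip_structures: list[StructurePointSet]) -> StructurePointSet:
    """Pick the most inferior ICD lead tip (smallest CoM along SI, z superior).

    Ties are broken deterministically by structure name order.
    """
    if len(tip_structures) == 0:
        raise ValueError("no ICD tip structures supplied")
    return min(tip_structures, key=lambda s: (float(s.com()[2]), s.name))
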