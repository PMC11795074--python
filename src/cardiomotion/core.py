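"""Shared spatial primitives: image grids and structure point sets.

Coordinate convention used throughout the package
-------------------------------------------------
Patient axes are fixed: ``x`` = right-left (RL), ``y`` = anterior-posterior
(AP, increasing toward posterior), ``z`` = superior-inferior (SI, increasing
toward superior).  Grids are axis-aligned; the world position of voxel index
``(i, j, k)`` is ``origin + index * spacing`` (voxel centers, 0-based
indices).  All world coordinates are in millimetres, all intensities in
Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np


class GridMismatchError(ValueError):
    """Two grids that must share shape/spacing/origin do not."""


class VolumeFormatError(ValueError):
    """A volume file could not be parsed or uses an unsupported layout."""


def _as_float3(value: Iterable[float], name: str) -> tuple[float, float, float]:
    arr = np.asarray(tuple(value), dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be 3 finite numbers, got {value!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VolumeImage:
    """A 3D scalar HU grid with voxel spacing and origin.

    ``intensities`` is indexed ``[ix, iy, iz]`` matching the x/y/z patient
    axes above.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing = _as_float3(self.spacing, "spacing")
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_float3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Convert mm points (N,3) or (3,) to continuous voxel indices."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        nx, ny, nz = self.shape
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        gx = ox + sx * np.arange(nx, dtype=float)
        gy = oy + sy * np.arange(ny, dtype=float)
        gz = oz + sz * np.arange(nz, dtype=float)
        out = np.empty(self.shape + (3,), dtype=float)
        out[..., 0] = gx[:, None, None]
        out[..., 1] = gy[None, :, None]
        out[..., 2] = gz[None, None, :]
        return out

    def same_grid_as(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


STRUCTURE_ROLES = ("CTV", "LV_segment", "ICD_tip", "myocardium")


@dataclass
class StructurePointSet:
    """A named cloud of contour points in patient-space millimetres."""

    name: str
    points: np.ndarray
    role: str = "myocardium"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.points.shape[0] < 1:
            raise ValueError(f"structure {self.name!r} has no points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"structure {self.name!r} has non-finite points")
        if self.role not in STRUCTURE_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {STRUCTURE_ROLES}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def com(self) -> np.ndarray:
        """Center of mass = unweighted mean of the contour points (mm)."""
        return self.points.mean(axis=0)


@dataclass
class Landmarks:
    """Anatomical landmarks defining the LV long axis and angular reference.

    ``apex``: epicardial apex tip; ``base_center``: center of the mitral/base
    plane; ``rv_insertion``: anterior RV-LV junction point, fixing the zero of
    the circumferential angle for the AHA 17-segment partition.
    """

    apex: np.ndarray
    base_center: np.ndarray
    rv_insertion: np.ndarray

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float).reshape(3)
        self.base_center = np.asarray(self.base_center, dtype=float).reshape(3)
        self.rv_insertion = np.asarray(self.rv_insertion, dtype=float).reshape(3)
        axis = self.apex - self.base_center
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValueError("apex and base_center coincide")
        d = self.rv_insertion - self.base_center
        transverse = d - (d @ axis) / norm**2 * axis
        if np.linalg.norm(transverse) < 1e-9:
            raise ValueError("rv_insertion lies on the long axis")

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector pointing from base toward apex."""
        axis = self.apex - self.base_center
        return axis / np.linalg.norm(axis)

    @property
    def long_axis_length(self) -> float:
        return float(np.linalg.norm(self.apex - self.base_center))
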