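"""Synthetic deforming-heart phantom with analytically known ground truth.

The phantom emulates a contrast-enhanced cardiac CT pair (end-diastole and
end-systole): a truncated-half-ellipsoid LV myocardium shell around a bright
blood pool, an anterior RV blood-pool crescent carrying a high-intensity ICD
lead whose tip is the tracked marker, and a CTV point cloud on the LV wall.
The end-systolic geometry is the image of the end-diastolic geometry under a
smooth, exactly invertible contraction:

* short-axis (radial) scaling by ``radial_scale`` about the long axis,
* long-axis scaling by ``longitudinal_scale`` about the base plane,
* twist: rotation about the long axis by ``twist_rate`` degrees per mm of
  end-diastolic long-axis distance from the base (apex rotates most, as in
  physiological LV torsion).

Because the transform is closed-form, the exact displacement of any material
point is available as ground truth for the registration and motion modules.

The myocardium carries a smooth material-attached HU heterogeneity
(band-limited Gaussian random field) emulating trabeculation and non-uniform
contrast enhancement.  This is not cosmetic: a perfectly homogeneous shell
makes motion tangential to the wall (twist, most of the longitudinal
shortening) invisible to any intensity-based registration (the aperture
problem), so a benchmark without wall texture cannot be recovered even by a
perfect algorithm.  The texture is evaluated in material (end-diastolic)
coordinates, so it deforms exactly with the ground-truth transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Landmarks, StructurePointSet, VolumeImage

ICD_TIP_RADIUS_MM = 2.0
N_CTV_POINTS = 250
N_SURFACE_POINTS = 400

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomCase",
    "analytic_displacement",
    "transform_points",
    "inverse_transform_points",
    "render_phase",
    "phase_masks",
    "make_landmarks",
    "make_ed_structures",
    "emit_case",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, deformation and imaging parameters of the phantom.

    Lengths in mm, intensities in HU, ``twist_rate`` in degrees per mm.
    ``epi_semi_axes`` are the two short-axis radii of the epicardial
    ellipsoid (a mildly elliptical cross-section, as for a real LV seated
    against the RV); ``long_axis_length`` is the base-to-apex distance.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_center: tuple[float, float, float] = (48.0, 48.0, 78.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    long_axis_length: float = 70.0
    epi_semi_axes: tuple[float, float] = (30.0, 26.0)
    wall_thickness: float = 10.0
    radial_scale: float = 0.9
    longitudinal_scale: float = 0.95
    twist_rate: float = 0.2
    hu_background: float = -50.0
    hu_myocardium: float = 150.0
    hu_blood_pool: float = 400.0
    hu_rv_pool: float = 300.0
    hu_icd_tip: float = 2000.0
    noise_sd: float = 5.0
    texture_amplitude: float = 40.0
    texture_correlation_mm: float = 6.0
    lead_length: float = 10.0
    ctv_center: tuple[float, float, float] = (71.0, 48.0, 53.0)
    ctv_radius: float = 8.0
    icd_tip_position: tuple[float, float, float] = (48.0, 20.0, 45.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.radial_scale <= 1.0):
            raise ValueError("radial_scale must be in (0, 1] (contraction)")
        if not (0.0 < self.longitudinal_scale <= 1.0):
            raise ValueError("longitudinal_scale must be in (0, 1] (contraction)")
        if not self.wall_thickness < min(self.epi_semi_axes):
            raise ValueError("wall_thickness must be smaller than the epicardial semi-axes")
        if min(self.spacing) <= 0:
            raise ValueError("spacings must be positive")
        if self.wall_thickness >= self.long_axis_length:
            raise ValueError("wall_thickness must be smaller than the long axis length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.texture_amplitude < 0 or self.texture_correlation_mm <= 0:
            raise ValueError("texture amplitude must be >= 0 and correlation length > 0")
        if self.lead_length < 0:
            raise ValueError("lead_length must be non-negative")
        lo, hi = self._bounding_box()
        extent_lo = np.zeros(3)
        extent_hi = (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)
        if np.any(lo < extent_lo - 1e-9) or np.any(hi > extent_hi + 1e-9):
            raise ValueError("epicardial ellipsoid does not fit inside the grid at end-diastole")

    # -- local frame -------------------------------------------------------

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal frame (e1, e2, w); w points base -> apex."""
        w = np.asarray(self.axis_direction, dtype=float)
        w = w / np.linalg.norm(w)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ w) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ w) * w
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(w, e1)
        return e1, e2, w

    def _bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        e1, e2, w = self.frame()
        a, b = self.epi_semi_axes
        c = self.long_axis_length
        center = np.asarray(self.base_center)
        corners = []
        for sa in (-a, a):
            for sb in (-b, b):
                for sc in (0.0, c):
                    corners.append(center + sa * e1 + sb * e2 + sc * w)
        corners = np.asarray(corners)
        return corners.min(axis=0), corners.max(axis=0)

    @property
    def apex(self) -> np.ndarray:
        _, _, w = self.frame()
        return np.asarray(self.base_center) + self.long_axis_length * w


# -- analytic deformation ---------------------------------------------------


def _decompose(points: np.ndarray, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split points into (long-axis distance l, transverse coords p1, p2)."""
    e1, e2, w = spec.frame()
    d = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(spec.base_center)
    return d @ w, d @ e1, d @ e2


def _recompose(l: np.ndarray, p1: np.ndarray, p2: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    e1, e2, w = spec.frame()
    return (
        np.asarray(spec.base_center)
        + l[..., None] * w
        + p1[..., None] * e1
        + p2[..., None] * e2
    )


def transform_points(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Map end-diastolic positions to end-systolic positions, T(p)."""
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    l, p1, p2 = _decompose(points, spec)
    ang = np.deg2rad(spec.twist_rate) * l
    ca, sa = np.cos(ang), np.sin(ang)
    q1 = spec.radial_scale * (ca * p1 - sa * p2)
    q2 = spec.radial_scale * (sa * p1 + ca * p2)
    out = _recompose(spec.longitudinal_scale * l, q1, q2, spec)
    return out[0] if single else out


def inverse_transform_points(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Exact inverse of :func:`transform_points` (ES position -> ED position)."""
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    l2, q1, q2 = _decompose(points, spec)
    l = l2 / spec.longitudinal_scale
    ang = np.deg2rad(spec.twist_rate) * l
    ca, sa = np.cos(ang), np.sin(ang)
    p1 = (ca * q1 + sa * q2) / spec.radial_scale
    p2 = (-sa * q1 + ca * q2) / spec.radial_scale
    out = _recompose(l, p1, p2, spec)
    return out[0] if single else out


def analytic_displacement(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Ground-truth displacement u(p) = T(p) - p in mm, defined everywhere."""
    points = np.asarray(points, dtype=float)
    return transform_points(points, spec) - points


# -- voxelisation ------------------------------------------------------------


def _inside_half_ellipsoid(
    l: np.ndarray, p1: np.ndarray, p2: np.ndarray, a: float, b: float, c: float
) -> np.ndarray:
    # truncated at the base plane (l >= 0), closed at the apex
    return (l >= 0) & ((p1 / a) ** 2 + (p2 / b) ** 2 + (l / c) ** 2 <= 1.0)


def _anterior_unit(spec: PhantomSpec) -> np.ndarray:
    """Anterior direction projected perpendicular to the long axis."""
    _, _, w = spec.frame()
    anterior = np.array([0.0, -1.0, 0.0])
    ref = anterior - (anterior @ w) * w
    if np.linalg.norm(ref) < 1e-9:
        ref = spec.frame()[0]
    return ref / np.linalg.norm(ref)


def _rv_geometry(spec: PhantomSpec) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Center and semi-axes of the anterior RV blood-pool half-ellipsoid."""
    a, b = spec.epi_semi_axes
    center = np.asarray(spec.base_center) + (b + 4.0) * _anterior_unit(spec)
    return center, (0.85 * a, 0.85 * b, 0.8 * spec.long_axis_length)


def _lead_points(spec: PhantomSpec) -> np.ndarray:
    """Centerline of the ICD lead: from the tip back toward the base."""
    _, _, w = spec.frame()
    n = max(2, int(np.ceil(spec.lead_length)) + 1)
    return np.asarray(spec.icd_tip_position) + np.linspace(0.0, spec.lead_length, n)[
        :, None
    ] * (-w)


@dataclass
class PhaseMasks:
    """Boolean voxel masks of one rendered phase."""

    myocardium: np.ndarray
    lv_pool: np.ndarray
    rv_pool: np.ndarray
    lead: np.ndarray


def phase_masks(spec: PhantomSpec, phase: str) -> PhaseMasks:
    """Voxel masks (myocardium, LV pool, RV pool, ICD lead) for one phase."""
    if phase not in ("ED", "ES"):
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")
    grid = VolumeImage(np.zeros(spec.grid_shape, dtype=np.float32), spec.spacing)
    coords = grid.voxel_centers().reshape(-1, 3)
    material = inverse_transform_points(coords, spec) if phase == "ES" else coords
    l, p1, p2 = _decompose(material, spec)
    a, b = spec.epi_semi_axes
    c = spec.long_axis_length
    w = spec.wall_thickness
    epi = _inside_half_ellipsoid(l, p1, p2, a, b, c)
    endo = _inside_half_ellipsoid(l, p1, p2, a - w, b - w, c - w)

    e1, e2, ax = spec.frame()
    rv_center, (ra, rb, rc) = _rv_geometry(spec)
    drv = material - rv_center
    rv = _inside_half_ellipsoid(drv @ ax, drv @ e1, drv @ e2, ra, rb, rc) & ~epi

    lead_pts = _lead_points(spec)
    if phase == "ES":
        lead_pts = transform_points(lead_pts, spec)
    dmin = np.min(
        np.linalg.norm(coords[:, None, :] - lead_pts[None, :, :], axis=2), axis=1
    )
    lead = dmin <= ICD_TIP_RADIUS_MM

    shape = spec.grid_shape
    return PhaseMasks(
        myocardium=(epi & ~endo).reshape(shape),
        lv_pool=endo.reshape(shape),
        rv_pool=rv.reshape(shape),
        lead=lead.reshape(shape),
    )


def _texture_coefficients(spec: PhantomSpec) -> np.ndarray:
    """Cubic-spline coefficients of the coarse material texture grid."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed) & 0x7FFFFFFF, 7]))
    shape = tuple(
        int(np.ceil((n - 1) * s / spec.texture_correlation_mm)) + 4
        for n, s in zip(spec.grid_shape, spec.spacing)
    )
    from scipy import ndimage

    return ndimage.spline_filter(rng.normal(0.0, 1.0, shape), order=3)


def _texture_at(points: np.ndarray, spec: PhantomSpec, coefficients: np.ndarray) -> np.ndarray:
    """Smooth material texture (HU) at mm points; band limit = correlation length."""
    from scipy import ndimage

    coords = np.atleast_2d(points) / spec.texture_correlation_mm + 2.0
    return spec.texture_amplitude * ndimage.map_coordinates(
        coefficients, coords.T, order=3, prefilter=False, mode="nearest"
    )


def render_phase(spec: PhantomSpec, phase: str) -> VolumeImage:
    """Voxelised HU image of one cardiac phase.

    Both the noise realisation and the material texture depend only on
    ``rng_seed`` (not on the phase), so an identity deformation yields
    bit-identical ED/ES volumes.
    """
    masks = phase_masks(spec, phase)
    grid = VolumeImage(np.zeros(spec.grid_shape, dtype=np.float32), spec.spacing)
    hu = np.full(spec.grid_shape, spec.hu_background, dtype=np.float64)
    hu[masks.rv_pool] = spec.hu_rv_pool
    hu[masks.lv_pool] = spec.hu_blood_pool
    myo = masks.myocardium
    if spec.texture_amplitude > 0 and np.any(myo):
        centers = grid.voxel_centers()[myo]
        material = inverse_transform_points(centers, spec) if phase == "ES" else centers
        hu[myo] = spec.hu_myocardium + _texture_at(material, spec, _texture_coefficients(spec))
    else:
        hu[myo] = spec.hu_myocardium
    hu[masks.lead] = spec.hu_icd_tip
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    return VolumeImage(hu.astype(np.float32), spec.spacing)


# -- structures and ground truth ---------------------------------------------

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _epicardial_surface_points(spec: PhantomSpec, n: int = N_SURFACE_POINTS) -> np.ndarray:
    """Deterministic spiral sampling of the epicardial surface."""
    k = np.arange(n)
    s = (k + 0.5) / n  # normalized long-axis position in [0, 1]
    theta = k * _GOLDEN_ANGLE
    a, b = spec.epi_semi_axes
    c = spec.long_axis_length
    r = np.sqrt(np.clip(1.0 - s**2, 0.0, 1.0))
    return _recompose(c * s, a * r * np.cos(theta), b * r * np.sin(theta), spec)


def _ctv_points(spec: PhantomSpec, n: int = N_CTV_POINTS) -> np.ndarray:
    """Points of the CTV sphere intersected with the myocardium shell."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 17]))
    a, b = spec.epi_semi_axes
    c, w = spec.long_axis_length, spec.wall_thickness
    center = np.asarray(spec.ctv_center)
    points: list[np.ndarray] = []
    for _ in range(200):
        raw = rng.uniform(-1.0, 1.0, size=(4 * n, 3))
        raw = raw[np.linalg.norm(raw, axis=1) <= 1.0] * spec.ctv_radius + center
        l, p1, p2 = _decompose(raw, spec)
        keep = _inside_half_ellipsoid(l, p1, p2, a, b, c) & ~_inside_half_ellipsoid(
            l, p1, p2, a - w, b - w, c - w
        )
        points.append(raw[keep])
        if sum(len(p) for p in points) >= n:
            break
    found = np.concatenate(points) if points else np.empty((0, 3))
    if found.shape[0] < max(10, n // 10):
        raise ValueError("ctv_center/ctv_radius do not intersect the myocardium shell")
    return found[:n]


def _icd_tip_points(spec: PhantomSpec) -> np.ndarray:
    center = np.asarray(spec.icd_tip_position, dtype=float)
    offsets = np.array(
        [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    return center + offsets


def make_ed_structures(spec: PhantomSpec) -> dict[str, StructurePointSet]:
    return {
        "LV_myocardium_surface": StructurePointSet(
            "LV_myocardium_surface", _epicardial_surface_points(spec), role="myocardium"
        ),
        "CTV": StructurePointSet("CTV", _ctv_points(spec), role="CTV"),
        "ICD_tip": StructurePointSet("ICD_tip", _icd_tip_points(spec), role="ICD_tip"),
    }


def make_landmarks(spec: PhantomSpec) -> Landmarks:
    # anterior RV insertion: where the (anterior) RV meets the LV wall
    rv_insertion = np.asarray(spec.base_center) + max(spec.epi_semi_axes) * 1.3 * _anterior_unit(spec)
    return Landmarks(apex=spec.apex, base_center=np.asarray(spec.base_center), rv_insertion=rv_insertion)


@dataclass
class GroundTruth:
    """Exact deformation products of one phantom case.

    ``es_structures`` are the ED structures mapped through the analytic
    transform point-by-point; ``field_mm`` is the displacement evaluated at
    every voxel center of the grid.
    """

    spec: PhantomSpec
    ed_structures: dict[str, StructurePointSet]
    es_structures: dict[str, StructurePointSet]
    landmarks: Landmarks

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        return analytic_displacement(points, self.spec)

    def field_mm(self) -> np.ndarray:
        grid = VolumeImage(np.zeros(self.spec.grid_shape, dtype=np.float32), self.spec.spacing)
        coords = grid.voxel_centers()
        return analytic_displacement(coords.reshape(-1, 3), self.spec).reshape(coords.shape)


def make_ground_truth(spec: PhantomSpec) -> GroundTruth:
    ed = make_ed_structures(spec)
    es = {
        name: StructurePointSet(s.name, transform_points(s.points, spec), role=s.role)
        for name, s in ed.items()
    }
    return GroundTruth(spec=spec, ed_structures=ed, es_structures=es, landmarks=make_landmarks(spec))


@dataclass
class PhantomCase:
    """A complete self-consistent test case."""

    spec: PhantomSpec
    ed: VolumeImage
    es: VolumeImage
    myo_mask: np.ndarray
    cavity_mask: np.ndarray
    ground_truth: GroundTruth

    @property
    def landmarks(self) -> Landmarks:
        return self.ground_truth.landmarks


def emit_case(spec: PhantomSpec, outdir: Path | str | None = None) -> PhantomCase:
    """Build (and optionally write to ``outdir``) one full phantom case.

    Masks are the noise-free end-diastolic geometry, mirroring contours drawn
    on the end-diastolic CT.
    """
    ed = render_phase(spec, "ED")
    es = render_phase(spec, "ES")
    masks = phase_masks(spec, "ED")
    truth = make_ground_truth(spec)
    case = PhantomCase(
        spec=spec,
        ed=ed,
        es=es,
        myo_mask=masks.myocardium,
        cavity_mask=masks.lv_pool,
        ground_truth=truth,
    )
    if outdir is not None:
        from . import io as cmio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cmio.write_volume(ed, outdir / "ed.nii.gz")
        cmio.write_volume(es, outdir / "es.nii.gz")
        cmio.write_volume(
            VolumeImage(case.myo_mask.astype(np.uint8), spec.spacing),
            outdir / "myo_mask.nii.gz",
        )
        cmio.write_volume(
            VolumeImage(case.cavity_mask.astype(np.uint8), spec.spacing),
            outdir / "cavity_mask.nii.gz",
        )
        cmio.write_true_field(truth, outdir / "true_field.nii.gz")
        cmio.write_point_sets(
            list(truth.ed_structures.values()), outdir / "structures_ed.json"
        )
        cmio.write_point_sets(
            list(truth.es_structures.values()), outdir / "structures_es.json"
        )
        cmio.write_landmarks(truth.landmarks, outdir / "landmarks.json")
    return case
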