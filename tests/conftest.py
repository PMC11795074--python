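"""Shared fixtures: phantom cases at several scales, registered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cardiomotion.phantom import PhantomSpec, emit_case
from cardiomotion.pipeline import run_case


def small_spec(**overrides) -> PhantomSpec:
    """A 48-voxel phantom: fast enough for per-test registration."""
    defaults = dict(
        grid_shape=(48, 48, 48),
        spacing=(1.25, 1.25, 1.25),
        base_center=(30.0, 30.0, 52.0),
        long_axis_length=40.0,
        epi_semi_axes=(17.0, 14.0),
        wall_thickness=6.0,
        ctv_center=(43.0, 30.0, 37.0),
        ctv_radius=5.0,
        icd_tip_position=(30.0, 15.0, 40.0),
        lead_length=8.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def axisymmetric_spec(**overrides) -> PhantomSpec:
    """Rotationally symmetric LV (equal short-axis radii) for symmetry oracles.

    The base center sits off the voxel lattice so that sector boundary
    planes do not coincide with lattice planes (which would bias the
    boundary tie-break toward two of the six sectors).
    """
    defaults = dict(
        grid_shape=(96, 96, 96),
        spacing=(1.0, 1.0, 1.0),
        base_center=(48.25, 47.65, 81.0),
        long_axis_length=60.0,
        epi_semi_axes=(26.0, 26.0),
        wall_thickness=9.0,
        ctv_center=(68.25, 47.65, 60.0),
        ctv_radius=5.0,
        icd_tip_position=(48.25, 16.0, 62.0),
        lead_length=8.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_case():
    return emit_case(small_spec())


@pytest.fixture(scope="session")
def small_result(small_case):
    """Full pipeline products for the small phantom (one registration)."""
    return run_case(
        small_case.ed,
        small_case.es,
        small_case.myo_mask,
        small_case.cavity_mask,
        list(small_case.ground_truth.ed_structures.values()),
        small_case.landmarks,
    )


@pytest.fixture(scope="session")
def default_case():
    """The default 96-voxel, 1 mm phantom (the acceptance-scale case)."""
    return emit_case(PhantomSpec())


@pytest.fixture(scope="session")
def default_result(default_case):
    return run_case(
        default_case.ed,
        default_case.es,
        default_case.myo_mask,
        default_case.cavity_mask,
        list(default_case.ground_truth.ed_structures.values()),
        default_case.landmarks,
    )


@pytest.fixture(scope="session")
def axisym_case():
    return emit_case(axisymmetric_spec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
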