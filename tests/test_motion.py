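"""Motion vectors: field sampling, CoM and per-point statistics, tip selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomotion.core import StructurePointSet
from cardiomotion.motion import (
    ClampError,
    com_motion,
    displace_points,
    pointwise_motion,
    sample_field_at_points,
    select_inferior_tip,
    summarize_structure,
)
from cardiomotion.phantom import transform_points
from cardiomotion.registration import DisplacementField

from conftest import small_spec


def _field(vectors, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return DisplacementField(np.asarray(vectors, dtype=float), spacing, origin)


def _uniform(shape, vec, **kw):
    vectors = np.zeros(tuple(shape) + (3,))
    vectors[...] = vec
    return _field(vectors, **kw)


class TestSampleField:
    def test_zero_field_gives_zero_vectors(self):
        field = _uniform((6, 6, 6), (0, 0, 0))
        vecs, clamped = sample_field_at_points(field, [[1.2, 3.4, 2.0]])
        assert np.all(vecs == 0.0) and clamped == 0

    def test_uniform_field_is_position_independent(self, rng):
        field = _uniform((8, 8, 8), (1.0, -2.0, 0.5), spacing=(2.0, 1.0, 0.5))
        pts = rng.uniform(0.5, 3.0, size=(40, 3))
        vecs, _ = sample_field_at_points(field, pts)
        assert np.allclose(vecs, [2.0, -2.0, 0.25], atol=1e-12)

    def test_linear_field_interpolates_between_voxel_centers(self):
        vectors = np.zeros((6, 4, 4, 3))
        vectors[..., 0] = np.arange(6)[:, None, None]  # u_x = ix
        field = _field(vectors)
        vecs, _ = sample_field_at_points(field, [[2.5, 1.0, 1.0]])
        assert np.allclose(vecs[0], [2.5, 0.0, 0.0], atol=1e-12)

    def test_outside_points_are_clamped_and_counted(self):
        field = _uniform((6, 6, 6), (1.0, 0.0, 0.0))
        vecs, clamped = sample_field_at_points(field, [[-5.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert clamped == 1
        assert np.allclose(vecs, [[1, 0, 0], [1, 0, 0]])

    def test_empty_point_list_rejected(self):
        with pytest.raises(ValueError):
            sample_field_at_points(_uniform((4, 4, 4), (0, 0, 0)), np.empty((0, 3)))

    def test_origin_offset_respected(self):
        vectors = np.zeros((6, 4, 4, 3))
        vectors[..., 0] = np.arange(6)[:, None, None]
        field = _field(vectors, origin=(10.0, 0.0, 0.0))
        vecs, _ = sample_field_at_points(field, [[12.0, 1.0, 1.0]])
        assert np.allclose(vecs[0], [2.0, 0.0, 0.0], atol=1e-12)


class TestComMotion:
    def test_no_displacement_gives_zero_record(self, rng):
        pts = rng.uniform(0, 10, (20, 3))
        rec = com_motion(pts, pts)
        assert rec.rl == rec.ap == rec.si == rec.magnitude_3d == 0.0

    def test_uniform_translation_pythagoras(self, rng):
        pts = rng.uniform(0, 10, (20, 3))
        rec = com_motion(pts, pts + np.array([3.0, 4.0, 0.0]))
        assert np.allclose([rec.rl, rec.ap, rec.si, rec.magnitude_3d], [3, 4, 0, 5], atol=1e-9)

    def test_phantom_ctv_com_matches_construction(self, small_case):
        truth = small_case.ground_truth
        rec = com_motion(truth.ed_structures["CTV"].points, truth.es_structures["CTV"].points)
        expected = truth.es_structures["CTV"].com() - truth.ed_structures["CTV"].com()
        assert np.allclose(rec.as_vector(), expected, atol=1e-12)

    def test_mismatched_cardinality_rejected(self):
        with pytest.raises(ValueError):
            com_motion(np.zeros((3, 3)), np.zeros((4, 3)))


class TestPointwiseMotion:
    def test_uniform_translation_has_zero_spread(self, rng):
        pts = rng.uniform(0, 10, (30, 3))
        stats = pointwise_motion(pts, pts + np.array([0.0, -2.0, 0.0]))
        assert stats["mag_3d"]["sd"] == 0.0
        assert np.isclose(stats["mag_3d"]["mean"], 2.0)
        assert np.isclose(stats["ap_abs"]["mean"], 2.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_mean_point_magnitude_bounds_com_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 20, (15, 3))
        displaced = pts + rng.normal(0, 2, (15, 3))
        stats = pointwise_motion(pts, displaced)
        rec = com_motion(pts, displaced)
        assert stats["mag_3d"]["mean"] >= rec.magnitude_3d - 1e-9

    def test_pure_rotation_moves_points_but_not_com(self):
        spec = small_spec(radial_scale=1.0, longitudinal_scale=1.0, twist_rate=2.0)
        base = np.asarray(spec.base_center)
        angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        ring = base + np.stack(
            [8 * np.cos(angles), 8 * np.sin(angles), np.full_like(angles, -20.0)], axis=1
        )
        displaced = transform_points(ring, spec)
        rec = com_motion(ring, displaced)
        stats = pointwise_motion(ring, displaced)
        assert rec.magnitude_3d < 1e-9
        assert stats["mag_3d"]["mean"] > 1.0


class TestSummarize:
    def test_summary_counts_and_magnitudes(self, small_case):
        spec = small_case.spec
        truth_vox = small_case.ground_truth.field_mm() / np.asarray(spec.spacing)
        field = DisplacementField(truth_vox, spec.spacing)
        ctv = small_case.ground_truth.ed_structures["CTV"]
        summary = summarize_structure(field, ctv)
        assert summary.n_points == ctv.n_points
        assert summary.n_clamped == 0
        expected = small_case.ground_truth.es_structures["CTV"].com() - ctv.com()
        # trilinear sampling of the smooth analytic field is near-exact
        assert np.linalg.norm(summary.com.as_vector() - expected) < 0.02

    def test_too_many_clamped_points_fails_the_run(self):
        field = _uniform((6, 6, 6), (0, 0, 0))
        outside = StructurePointSet("stray", np.full((10, 3), 50.0), role="CTV")
        with pytest.raises(ClampError):
            summarize_structure(field, outside)


class TestTipSelection:
    def test_single_tip_returned_unchanged(self):
        tip = StructurePointSet("tip", [[0.0, 0.0, 10.0]], role="ICD_tip")
        assert select_inferior_tip([tip]) is tip

    def test_most_inferior_tip_wins(self):
        hi = StructurePointSet("rv_tip", [[0.0, 0.0, 60.0]], role="ICD_tip")
        lo = StructurePointSet("ra_tip", [[0.0, 0.0, 40.0]], role="ICD_tip")
        assert select_inferior_tip([hi, lo]) is lo

    def test_tie_broken_by_name_order(self):
        a = StructurePointSet("tip_b", [[0.0, 0.0, 40.0]], role="ICD_tip")
        b = StructurePointSet("tip_a", [[5.0, 5.0, 40.0]], role="ICD_tip")
        assert select_inferior_tip([a, b]).name == "tip_a"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_inferior_tip([])


def test_displace_points_round_trip(small_case):
    spec = small_case.spec
    truth_vox = small_case.ground_truth.field_mm() / np.asarray(spec.spacing)
    field = DisplacementField(truth_vox, spec.spacing)
    pts = small_case.ground_truth.ed_structures["CTV"].points
    displaced, clamped = displace_points(field, pts)
    assert clamped == 0
    expected = small_case.ground_truth.es_structures["CTV"].points
    assert np.abs(displaced - expected).max() < 0.05
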