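"""Similarity formulas, Wilcoxon signed-rank, Euclidean distances, ROI building."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cardiomotion.concordance import (
    ConstantInputError,
    MotionSeries,
    RoiIntensityPair,
    build_evaluation_roi,
    evaluate_registration,
    motion_euclidean_distance,
    mse,
    pcc,
    wilcoxon_signed_rank,
)
from cardiomotion.registration import DisplacementField


def _brute_mse(x, y):
    return sum((a - b) ** 2 for a, b in zip(x, y)) / len(x)


def _brute_pcc(x, y):
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def _brute_wilcoxon(diffs):
    """Exact two-sided p by full enumeration over sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(ranks)
    low = high = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        low += w <= w_obs + 1e-9
        high += w >= w_obs - 1e-9
    total = 2**n
    return w_obs, min(1.0, 2.0 * min(low / total, high / total))


class TestMse:
    def test_identical_vectors_give_zero(self, rng):
        x = rng.normal(0, 100, 50)
        assert mse(x, x) == 0.0

    def test_hand_example(self):
        assert mse([0.0, 0.0], [10.0, 20.0]) == 250.0

    def test_constant_offset_reduces_to_square(self, rng):
        x = rng.normal(0, 50, 64)
        assert np.isclose(mse(x, x + 7.0), 49.0, atol=1e-9)

    def test_accepts_roi_pair(self):
        pair = RoiIntensityPair([1.0, 2.0], [2.0, 4.0])
        assert mse(pair) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([1.0, 2.0], [1.0])


class TestPcc:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, p = pcc(x, x)
        assert r == 1.0 and p == 0.0

    def test_perfect_anticorrelation_affine(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, _ = pcc(x, -2.0 * x + 7.0)
        assert r == -1.0

    def test_hand_example_matches_brute_force(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        r, _ = pcc(x, y)
        assert abs(r - _brute_pcc(x, y)) < 1e-12

    def test_matches_brute_force_and_scipy_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(0, 50, n)
            y = rng.normal(0, 50, n)
            r, p = pcc(x, y)
            assert abs(r - _brute_pcc(x, y)) < 1e-12
            ref = sps.pearsonr(x, y)
            assert abs(r - ref.statistic) < 1e-12
            assert abs(p - ref.pvalue) < 1e-9

    def test_p_value_is_t_transform(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 7.0])
        r, p = pcc(x, y)
        t = r * np.sqrt((len(x) - 2) / (1 - r * r))
        assert np.isclose(p, 2 * sps.t.sf(abs(t), len(x) - 2), atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    def test_six_positive_differences_exact_tail(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        w, p = wilcoxon_signed_rank(a + np.array([1, 2, 3, 4, 5, 6.0]), a)
        assert w == 21.0
        assert np.isclose(p, 2.0 / 64.0, atol=1e-12)

    def test_exact_branch_equals_full_enumeration(self, rng):
        for n in range(5, 13):
            # integer differences induce rank ties; no zeros, so n is preserved
            d = rng.integers(1, 5, n) * rng.choice([-1.0, 1.0], n)
            w, p = wilcoxon_signed_rank(d, np.zeros(n))
            w_ref, p_ref = _brute_wilcoxon(d)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(0, 5, 10)
            b = a + rng.normal(0, 2, 10)
            if np.any(a == b) or len(np.unique(np.abs(a - b))) < 10:
                continue
            _, p = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, method="exact")
            assert np.isclose(p, ref.pvalue, atol=1e-12)

    def test_normal_approximation_close_to_exact_at_n12(self, rng):
        for _ in range(20):
            a = rng.normal(0, 5, 12)
            b = a + rng.normal(0.5, 2, 12)
            if np.all(a == b):
                continue
            _, p_exact = wilcoxon_signed_rank(a, b, exact_max_n=15)
            _, p_approx = wilcoxon_signed_rank(a, b, exact_max_n=5)
            assert abs(p_exact - p_approx) < 0.02

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])

    def test_motion_series_inputs(self):
        a = MotionSeries(list("abcdef"), [3.0, 4.1, 5.2, 2.9, 4.4, 3.3])
        b = MotionSeries(list("abcdef"), [2.0, 3.0, 4.0, 2.0, 3.0, 2.0])
        w, p = wilcoxon_signed_rank(a, b)
        assert 0.0 < p <= 1.0


class TestEuclideanDistance:
    def test_identical_series_give_zero(self):
        assert motion_euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_case_is_absolute_difference(self):
        assert motion_euclidean_distance([5.0], [2.0]) == 3.0

    def test_pythagorean_two_cases(self):
        assert motion_euclidean_distance([3.0, 4.0], [0.0, 0.0]) == 5.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            motion_euclidean_distance([1.0], [1.0, 2.0])


class TestEvaluationRoi:
    def _mask(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:9, 4:9, 4:9] = True
        return mask

    def _uniform_field(self, shape, vec):
        vectors = np.zeros(tuple(shape) + (3,))
        vectors[...] = vec
        return DisplacementField(vectors, (1.0, 1.0, 1.0))

    def test_zero_field_keeps_the_mask(self):
        mask = self._mask()
        roi = build_evaluation_roi(mask, self._uniform_field(mask.shape, (0, 0, 0)))
        assert np.array_equal(roi, mask)

    def test_uniform_shift_unions_mask_and_shifted_copy(self):
        mask = self._mask()
        roi = build_evaluation_roi(mask, self._uniform_field(mask.shape, (2.0, 0.0, 0.0)))
        expected = mask | np.roll(mask, 2, axis=0)
        assert np.array_equal(roi, expected)
        assert mask.sum() <= roi.sum() <= 2 * mask.sum()

    def test_phantom_contraction_roi_is_superset(self, small_case, small_result):
        roi = build_evaluation_roi(small_case.myo_mask, small_result.field)
        assert roi.sum() >= small_case.myo_mask.sum()
        assert np.all(roi[small_case.myo_mask])

    def test_empty_mask_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            build_evaluation_roi(mask, self._uniform_field(mask.shape, (0, 0, 0)))


class TestRegistrationQuality:
    def test_registration_improves_similarity_on_phantom(self, small_case, small_result):
        metrics = small_result.roi_metrics
        assert metrics.mse_after < metrics.mse_before
        assert metrics.pcc_after > metrics.pcc_before
        assert metrics.pcc_p_after < 0.05

    def test_evaluate_registration_uses_the_roi_only(self, small_case, small_result):
        roi = build_evaluation_roi(small_case.myo_mask, small_result.field)
        metrics = evaluate_registration(
            small_case.es, small_case.ed, small_result.displaced_ed, roi
        )
        i_fixed = small_case.es.intensities[roi]
        i_moving = small_case.ed.intensities[roi]
        assert metrics.mse_before == pytest.approx(_brute_mse(i_fixed, i_moving))
        assert metrics.n_voxels == int(roi.sum())
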