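import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mokkenpy as mp
from mokkenpy.data import DataError

from .oracles import brute_coef_h, brute_covmax


class TestPairCoefficients:
    def test_covariance_hand_values(self):
        assert mp.pair_covariance([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(0.25)
        assert mp.pair_covariance([0, 1], [1, 0]) == pytest.approx(-0.25)
        assert mp.pair_covariance([1, 1, 1], [0, 1, 2]) == 0.0

    def test_covariance_length_mismatch(self):
        with pytest.raises(DataError):
            mp.pair_covariance([0, 1], [0, 1, 1])

    def test_covmax_binary_hand_value(self):
        # 3/10 and 5/10 positives: overlap 3 -> E[XY]max = 0.3
        assert mp.pair_covmax([7, 3], [5, 5]) == pytest.approx(0.3 - 0.3 * 0.5)

    def test_covmax_identical_half_split(self):
        assert mp.pair_covmax([5, 5], [5, 5]) == pytest.approx(0.25)

    def test_covmax_constant_item_is_zero(self):
        assert mp.pair_covmax([10, 0], [4, 6]) == 0.0

    def test_covmax_total_mismatch(self):
        with pytest.raises(DataError, match="totals"):
            mp.pair_covmax([5, 5], [4, 5])

    def test_covmax_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(4, 13)
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            fx = np.bincount(x, minlength=x.max() + 1)
            fy = np.bincount(y, minlength=y.max() + 1)
            assert mp.pair_covmax(fx, fy) == pytest.approx(brute_covmax(x, y))


class TestCoefH:
    def test_guttman_scale_is_perfect(self, guttman_matrix):
        res = mp.coef_h(guttman_matrix)
        assert res.h == pytest.approx(1.0)
        off = ~np.eye(res.hij.shape[0], dtype=bool)
        np.testing.assert_allclose(res.hij[off], 1.0)
        assert res.classification == "strong"

    def test_independent_items_near_zero(self):
        cfg = mp.SyntheticConfig(
            n=50000, items=mp.constant_binary([0.2, 0.4, 0.6, 0.8]), seed=5
        )
        res = mp.coef_h(mp.generate(cfg))
        assert abs(res.h) < 0.02
        assert res.classification == "unscalable"

    def test_zero_variance_item_named(self):
        values = np.column_stack([np.zeros(10, int), np.arange(10) % 2])
        with pytest.raises(DataError, match="item1"):
            mp.coef_h(values)

    def test_single_item_rejected(self):
        with pytest.raises(DataError):
            mp.coef_h(np.array([[0], [1]]))

    def test_matches_enumeration_oracle_on_random_instances(self):
        from .conftest import random_small_matrix

        rng = np.random.default_rng(11)
        for _ in range(100):
            values = random_small_matrix(rng)
            res = mp.coef_h(values)
            hij, hi, h = brute_coef_h(values)
            np.testing.assert_allclose(res.h, h, atol=1e-12)
            np.testing.assert_allclose(res.hi, hi, atol=1e-12)
            mask = np.isfinite(hij)
            np.testing.assert_allclose(res.hij[mask], hij[mask], atol=1e-12)

    def test_mediant_property(self, dmm_matrix):
        res = mp.coef_h(dmm_matrix)
        assert res.hi.min() - 1e-12 <= res.h <= res.hi.max() + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_shuffle_and_reversal_invariance(self, seed):
        from .conftest import random_small_matrix

        rng = np.random.default_rng(seed)
        values = random_small_matrix(rng)
        res = mp.coef_h(values)
        shuffled = values[rng.permutation(values.shape[0])]
        assert mp.coef_h(shuffled).h == pytest.approx(res.h)
        reversed_scores = values.max(axis=0)[None, :] - values
        assert mp.coef_h(reversed_scores).h == pytest.approx(res.h)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_item_permutation_consistency(self, seed):
        from .conftest import random_small_matrix

        rng = np.random.default_rng(seed)
        values = random_small_matrix(rng)
        perm = rng.permutation(values.shape[1])
        res = mp.coef_h(values)
        res_p = mp.coef_h(values[:, perm])
        assert res_p.h == pytest.approx(res.h)
        np.testing.assert_allclose(res_p.hi, res.hi[perm], atol=1e-12)


class TestCoefHT:
    def test_guttman_transpose_is_perfect(self, guttman_matrix):
        assert mp.coef_ht(guttman_matrix) == pytest.approx(1.0)

    def test_identical_marginals_independent_residuals_near_zero(self):
        cfg = mp.SyntheticConfig(
            n=3000, items=mp.constant_binary([0.5] * 5), seed=17
        )
        assert abs(mp.coef_ht(mp.generate(cfg))) < 0.05

    def test_accuracy_band_of_0_31(self):
        assert mp.classify_ht(0.31) == "low accuracy"
        assert mp.classify_ht(0.29) == "inaccurate"
        assert mp.classify_ht(0.45) == "medium accuracy"
        assert mp.classify_ht(0.55) == "high accuracy"

    def test_all_identical_respondents_error(self):
        values = np.tile([0, 1, 1], (10, 1))
        with pytest.raises(DataError):
            mp.coef_ht(values)


class TestStrengthBands:
    @pytest.mark.parametrize(
        "h,label",
        [(0.2, "unscalable"), (0.35, "weak"), (0.45, "medium"), (0.61, "strong")],
    )
    def test_classification(self, h, label):
        assert mp.classify_h(h) == label


class TestPositivityScreen:
    def test_associated_pair_rejected(self, dmm_matrix):
        table = mp.hij_positivity_test(dmm_matrix, alpha=0.05)
        assert table["significant"].all()

    def test_independent_pair_false_positive_rate(self):
        rejections = 0
        for seed in range(200):
            cfg = mp.SyntheticConfig(
                n=1000, items=mp.constant_binary([0.4, 0.6]), seed=seed
            )
            table = mp.hij_positivity_test(mp.generate(cfg), alpha=0.05)
            rejections += int(table["significant"].iloc[0])
        # Binomial(200, 0.05): central 99.9% range roughly [1, 21]
        assert 0 <= rejections <= 22

    def test_degenerate_pair_flagged_not_tested(self):
        values = np.column_stack([np.zeros(20, int), np.arange(20) % 2])
        table = mp.hij_positivity_test(values)
        assert table["degenerate"].iloc[0]
        assert not table["significant"].iloc[0]

    def test_tiny_sample_flagged(self):
        values = np.array([[0, 0], [1, 1], [0, 1]])
        table = mp.hij_positivity_test(values)
        assert table["small_sample"].all()


class TestEstimator:
    def test_fitted_attributes(self, dmm_matrix):
        est = mp.ScalabilityAnalysis(compute_ht=True).fit(dmm_matrix)
        assert 0 < est.h_ < 1
        assert est.h_i_.shape == (6,)
        assert est.classification_ in {"unscalable", "weak", "medium", "strong"}
        assert np.isfinite(est.ht_)

    def test_get_params_roundtrip(self):
        est = mp.ScalabilityAnalysis(compute_ht=True)
        assert est.get_params() == {"compute_ht": True}
        est.set_params(compute_ht=False)
        assert not est.compute_ht
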