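import numpy as np
import pytest

import mokkenpy as mp
from mokkenpy.data import DataError
from mokkenpy.grouping import group_restscores


def matrix_with_group_proportions(proportions, group_size=40):
    """Binary focal item with controlled endorsement per restscore group.

    Two companion items generate restscores 0..3; the focal item endorses
    with the requested proportion in each restscore group.
    """
    rows = []
    for g, prop in enumerate(proportions):
        b = min(g, 1)
        c = g - b
        n_pos = int(round(prop * group_size))
        for r in range(group_size):
            rows.append([1 if r < n_pos else 0, b, c])
    return np.asarray(rows)


class TestDefaultMinsize:
    @pytest.mark.parametrize(
        "n,expected",
        [(773, 77), (8643, 864), (300, 60), (450, 90), (100, 50),
         (240, 80), (501, 50), (500, 100)],
    )
    def test_printed_rule(self, n, expected):
        assert mp.default_minsize(n) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(DataError):
            mp.default_minsize(0)


class TestRestscoreGrouping:
    def test_merging_respects_minsize(self):
        rng = np.random.default_rng(2)
        rest = rng.integers(0, 6, 500)
        grp = group_restscores(rest, minsize=60)
        assert (grp.group_sizes >= 60).all()
        assert grp.group_sizes.sum() == 500

    def test_minsize_one_keeps_every_value(self):
        rest = np.repeat([0, 1, 3, 4], 5)
        grp = group_restscores(rest, minsize=1)
        assert grp.n_groups == 4

    def test_single_restscore_value_errors(self):
        with pytest.raises(DataError, match="restscore groups"):
            group_restscores(np.full(100, 3), minsize=10)

    def test_build_for_focal_item(self, dmm_matrix):
        grp = mp.build_restscore_groups(dmm_matrix, focal_item=0)
        assert grp.n_groups >= 2
        assert grp.group_sizes.sum() == 2000


class TestCheckMonotonicity:
    def test_clean_dmm_data_has_no_violations(self, dmm_matrix):
        report = mp.check_monotonicity(dmm_matrix)
        assert (report.summary["#vi"] == 0).all()
        assert (report.summary["#zsig"] == 0).all()
        assert (report.summary["crit"] == 0).all()

    def test_active_comparisons_formula(self):
        # 4 restscore groups -> 4*3/2 = 6 active comparisons per binary item
        values = matrix_with_group_proportions([0.2, 0.4, 0.6, 0.9])
        report = mp.check_monotonicity(
            values, mp.CheckSettings(minsize=1, minvi=0.03)
        )
        focal = report.summary.iloc[0]
        assert focal["n_groups"] == 4
        assert focal["#ac"] == 6

    @pytest.mark.parametrize("minvi,expected_vi", [(0.03, 1), (0.06, 0)])
    def test_hand_built_dip_counted_once(self, minvi, expected_vi):
        values = matrix_with_group_proportions([0.2, 0.5, 0.45, 0.9])
        report = mp.check_monotonicity(
            values, mp.CheckSettings(minsize=1, minvi=minvi)
        )
        focal = report.summary.iloc[0]
        assert focal["#ac"] == 6
        assert focal["#vi"] == expected_vi

    def test_strictly_increasing_deterministic_data_clean(self):
        values = matrix_with_group_proportions([0.1, 0.3, 0.6, 0.9])
        for minvi in [0.0, 0.03, 0.2]:
            rep = mp.check_monotonicity(
                values, mp.CheckSettings(minsize=1, minvi=minvi)
            )
            assert rep.summary.iloc[0]["#vi"] == 0

    def test_vi_nonincreasing_in_minvi_and_count_ordering(self):
        rng = np.random.default_rng(23)
        values = rng.integers(0, 2, size=(300, 5))
        previous = None
        for minvi in [0.0, 0.02, 0.05, 0.1, 0.2]:
            rep = mp.check_monotonicity(
                values, mp.CheckSettings(minsize=30, minvi=minvi)
            ).summary
            assert (rep["#zsig"] <= rep["#vi"]).all()
            assert (rep["#vi"] <= rep["#ac"]).all()
            total_vi = rep["#vi"].sum()
            if previous is not None:
                assert total_vi <= previous
            previous = total_vi

    def test_unimodal_item_flagged(self, dmm_config):
        flagged = 0
        for seed in range(5):
            cfg = mp.SyntheticConfig(
                n=dmm_config.n, items=dmm_config.items, seed=seed
            )
            cfg = mp.inject_unimodal_item(cfg, 2)
            rep = mp.check_monotonicity(mp.generate(cfg))
            flagged += rep.summary.iloc[2]["#zsig"] > 0
        assert flagged >= 4

    def test_polytomous_ac_counts_per_step(self):
        rng = np.random.default_rng(3)
        theta = rng.standard_normal(1500)
        items = mp.graded_items(
            [[-1.0, 0.0, 1.0]] * 4, discrimination=1.5
        )
        from mokkenpy.synthetic import _sample_items

        values = _sample_items(items, theta, rng)
        rep = mp.check_monotonicity(values, mp.CheckSettings(minsize=150))
        # each item: 3 steps x R(R-1)/2 comparisons
        for _, row in rep.summary.iterrows():
            r = row["n_groups"]
            assert row["#ac"] == 3 * r * (r - 1) // 2


class TestPlotData:
    def test_series_shape_and_dip(self):
        values = matrix_with_group_proportions([0.2, 0.5, 0.45, 0.9])
        rep = mp.check_monotonicity(values, mp.CheckSettings(minsize=1))
        series = mp.export_monotonicity_plotdata(rep)
        focal = series[(series["item"] == "item1") & (series["step"] == 1)]
        assert len(focal) == 4
        np.testing.assert_allclose(
            focal["proportion"].to_numpy(), [0.2, 0.5, 0.45, 0.9]
        )

    def test_monotone_item_series_nondecreasing(self, dmm_matrix):
        rep = mp.check_monotonicity(dmm_matrix)
        series = mp.export_monotonicity_plotdata(rep)
        item = series[(series["item"] == "item1") & (series["step"] == 1)]
        props = item["proportion"].to_numpy()
        assert (np.diff(props) > -0.03).all()


class TestEstimator:
    def test_fit_exposes_summary(self, dmm_matrix):
        est = mp.MonotonicityCheck(minvi=0.03).fit(dmm_matrix)
        assert set(["Label", "#ac", "#vi", "#zsig", "crit"]).issubset(
            est.summary_.columns
        )
        assert est.get_params()["minvi"] == 0.03
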