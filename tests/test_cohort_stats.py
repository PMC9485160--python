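import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from skipquant.cohort_stats import (
    FrequencyTable,
    build_frequency_table,
    compare_conditions,
    exact_null_counts,
    format_p,
    mw_exact,
    recovery_score,
)


def enumerate_u_counts(n1: int, n2: int) -> np.ndarray:
    """Independent oracle: distribution of U over all C(n1+n2, n1) rank
    assignments, by direct enumeration."""
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1)
    for x_ranks in itertools.combinations(range(n), n1):
        y_ranks = [r for r in range(n) if r not in x_ranks]
        u = sum(1 for xr in x_ranks for yr in y_ranks if xr > yr)
        counts[u] += 1
    return counts


class TestExactNull:
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (3, 7), (4, 6), (5, 5)])
    def test_matches_full_enumeration(self, n1, n2):
        np.testing.assert_array_equal(exact_null_counts(n1, n2), enumerate_u_counts(n1, n2))

    @pytest.mark.parametrize("n1,n2", [(3, 8), (4, 9), (2, 11)])
    def test_sums_to_binomial_and_symmetric(self, n1, n2):
        counts = exact_null_counts(n1, n2)
        assert counts.sum() == math.comb(n1 + n2, n1)
        np.testing.assert_array_equal(counts, counts[::-1])


class TestMWExact:
    def test_complete_separation_3v8_is_exact_floor(self):
        res = mw_exact([1, 2, 3], [4, 5, 6, 7, 8, 9, 10, 11])
        assert res.method == "exact"
        assert res.U == 0
        assert res.p_two_sided == pytest.approx(2 / 165)
        assert format_p(res.p_two_sided) == "0.012"
        # the reversed direction gives the same two-sided p
        res_rev = mw_exact([4, 5, 6, 7, 8, 9, 10, 11], [1, 2, 3])
        assert res_rev.p_two_sided == pytest.approx(2 / 165)

    def test_u_equal_two_for_3v8(self):
        # exactly 2 discordant cross-pairs
        x, y = [1, 2, 5], [3, 4, 6, 7, 8, 9, 10, 11]
        res = mw_exact(x, y)
        assert res.U == 2
        assert res.p_two_sided == pytest.approx(8 / 165)
        assert format_p(res.p_two_sided) == "0.048"

    def test_all_tied_gives_p_one_with_flagged_method(self):
        res = mw_exact([5.0, 5.0, 5.0], [5.0] * 8)
        assert res.p_two_sided == 1.0
        assert res.method == "normal_tie_corrected"

    def test_floor_p_for_3v8_is_minimum_over_all_u(self):
        counts = exact_null_counts(3, 8)
        total = counts.sum()
        ps = []
        for u in range(25):
            lower = counts[: u + 1].sum() / total
            upper = counts[u:].sum() / total
            ps.append(min(1.0, 2 * min(lower, upper)))
        assert min(ps) == pytest.approx(2 / 165)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_exact_on_untied_data(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 9))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        ours = mw_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_large_samples_fall_back_to_normal(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = mw_exact(x, y)
        assert res.method == "normal_tie_corrected"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mw_exact([], [1.0])


class TestFrequencyTable:
    def test_build_from_annotations(self):
        ann = pd.DataFrame(
            {
                "barcode": [f"b{i}" for i in range(4)],
                "sample": ["s1"] * 4,
                "condition": ["WT"] * 4,
                "cluster": ["A", "A", "B", "C"],
            }
        )
        ft = build_frequency_table(ann)
        assert list(ft.values.loc["s1", ["A", "B", "C"]]) == [50.0, 25.0, 25.0]

    def test_single_type_sample(self):
        ann = pd.DataFrame(
            {
                "barcode": ["b1"],
                "sample": ["s1"],
                "condition": ["WT"],
                "cluster": ["A"],
            }
        )
        ft = build_frequency_table(ann)
        assert ft.values.loc["s1", "A"] == 100.0

    def test_rows_must_sum_to_100(self):
        values = pd.DataFrame({"A": [40.0], "B": [40.0]}, index=["s1"])
        with pytest.raises(ValueError, match="sum to 100"):
            FrequencyTable(values, pd.Series(["WT"], index=["s1"]))

    def test_tsv_round_trip(self, tmp_path):
        values = pd.DataFrame(
            {"A": [60.0, 30.0], "B": [40.0, 70.0]}, index=["s1", "s2"]
        )
        ft = FrequencyTable(values, pd.Series(["WT", "mdx"], index=["s1", "s2"]))
        path = tmp_path / "ft.tsv"
        ft.to_tsv(path)
        back = FrequencyTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.values, ft.values)
        pd.testing.assert_series_equal(back.conditions, ft.conditions)


def _ft(wt_rows, mdx_rows, cell_types=("T",)):
    rows = wt_rows + mdx_rows
    conds = ["WT"] * len(wt_rows) + ["mdx"] * len(mdx_rows)
    samples = [f"s{i}" for i in range(len(rows))]
    values = pd.DataFrame(rows, index=samples, columns=list(cell_types))
    # pad with a filler type so rows sum to 100
    values["other"] = 100.0 - values.sum(axis=1)
    return FrequencyTable(values, pd.Series(conds, index=samples))


class TestCompareConditions:
    def test_uniformly_higher_group_hits_exact_floor(self):
        ft = _ft([[30.0], [31.0], [32.0]], [[float(i)] for i in range(8)])
        out = compare_conditions(ft, "WT", "mdx").set_index("cell_type")
        assert out.loc["T", "direction"] == "increase"
        assert out.loc["T", "p"] == pytest.approx(2 / 165)
        # filler column moves the opposite way
        assert out.loc["other", "direction"] == "decrease"

    def test_identical_groups_give_p_one(self):
        ft = _ft([[10.0]] * 3, [[10.0]] * 8)
        out = compare_conditions(ft, "WT", "mdx")
        assert (out["p"] == 1.0).all()

    def test_bh_adjustment_is_monotone_and_order_preserving(self):
        rng = np.random.default_rng(9)
        wt = [[float(v)] for v in rng.uniform(20, 40, size=3)]
        mdx = [[float(v)] for v in rng.uniform(10, 50, size=8)]
        ft = _ft(wt, mdx)
        out = compare_conditions(ft, "WT", "mdx", adjust="bh")
        assert (out["p_bh"] >= out["p"] - 1e-12).all()
        p = out["p"].to_numpy()
        p_bh = out["p_bh"].to_numpy()
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] <= p[j]:
                    assert p_bh[i] <= p_bh[j] + 1e-12

    def test_missing_condition_raises(self):
        ft = _ft([[10.0]] * 3, [[10.0]] * 8)
        with pytest.raises(ValueError, match="treated"):
            compare_conditions(ft, "WT", "treated")


class TestRecoveryScore:
    def _three_condition_ft(self, wt, disease, treated):
        rows = [[wt], [disease], [treated]]
        conds = ["WT", "mdx", "mdx_e23AON"]
        samples = ["s1", "s2", "s3"]
        values = pd.DataFrame(rows, index=samples, columns=["T"])
        values["other"] = 100.0 - values["T"]
        ft = FrequencyTable(values, pd.Series(conds, index=samples))
        return ft

    def test_partial_return_toward_wt_is_recovered(self):
        ft = self._three_condition_ft(10.0, 2.0, 6.0)
        call = recovery_score(ft, "WT", "mdx", "mdx_e23AON")[0]
        assert call.direction_vs_wt == "decrease"
        assert call.recovered is True

    def test_moving_further_away_is_not_recovered(self):
        ft = self._three_condition_ft(10.0, 2.0, 1.0)
        call = recovery_score(ft, "WT", "mdx", "mdx_e23AON")[0]
        assert call.recovered is False

    def test_no_disease_deviation_is_undefined(self):
        ft = self._three_condition_ft(10.0, 10.0, 12.0)
        call = recovery_score(ft, "WT", "mdx", "mdx_e23AON")[0]
        assert call.direction_vs_wt == "none"
        assert call.recovered is None
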