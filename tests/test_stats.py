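"""Statistics layer: ANOVA/Tukey against textbook oracles, averaging, narrowing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agnorfract import (
    aggregate,
    fd_frequency_analysis,
    narrow_filter,
    one_way_anova,
    pearson_compartments,
    tukey_hsd,
)
from _stat_oracles import anova_by_sums_of_squares, tukey_kramer_pvalues


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        res = one_way_anova({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t**2, abs=1e-10)

    def test_hand_computed_fixture(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0], "C": [6.0, 7.0, 8.0]}
        res = one_way_anova(groups)
        f, df_b, df_w, p = anova_by_sums_of_squares(groups)
        assert res.f_stat == pytest.approx(f, abs=1e-8)
        assert (res.df_between, res.df_within) == (df_b, df_w)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_degrees_of_freedom_bookkeeping(self):
        res = one_way_anova({"a": [1, 2], "b": [3, 4], "c": [5, 6, 7]})
        assert res.df_between == 2
        assert res.df_within == 7 - 3

    def test_undersized_group_failure_names_it(self):
        with pytest.raises(ValueError, match="tiny"):
            one_way_anova({"a": [1, 2, 3], "tiny": [1.0]})


class TestTukeyHsd:
    def test_identical_groups_nothing_significant(self):
        t = tukey_hsd({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}, alpha=0.05)
        assert not t["significant"].any()

    def test_extreme_shift_all_pairs_significant(self):
        rng = np.random.default_rng(2)
        base = {f"g{i}": rng.normal(0, 1, 20) for i in range(3)}
        base["shifted"] = rng.normal(10, 1, 20)
        t = tukey_hsd(base, alpha=0.01)
        hits = t[(t.group_a == "shifted") | (t.group_b == "shifted")]
        assert hits["significant"].all()

    def test_adjusted_p_at_least_unadjusted_pairwise_t(self):
        # the unadjusted comparison shares the Tukey test's pooled MSW and df
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = {f"g{i}": rng.normal(rng.normal(0, 0.5), 1, int(rng.integers(5, 15))) for i in range(4)}
            n = sum(len(v) for v in groups.values())
            k = len(groups)
            msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (n - k)
            t = tukey_hsd(groups)
            for _, row in t.iterrows():
                a, b = groups[row.group_a], groups[row.group_b]
                t_stat = abs(row.mean_diff) / np.sqrt(msw * (1 / len(a) + 1 / len(b)))
                p_t = 2 * sps.t.sf(t_stat, n - k)
                if p_t > 1e-6:  # below that the studentized-range integral underflows to 0
                    assert row.p_adj >= p_t - 1e-10

    def test_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(11)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, int(rng.integers(4, 12))) for i in range(5)}
        oracle = tukey_kramer_pvalues({k: list(v) for k, v in groups.items()})
        t = tukey_hsd(groups)
        for _, row in t.iterrows():
            key = (row.group_a, row.group_b)
            key = key if key in oracle else key[::-1]
            assert row.p_adj == pytest.approx(oracle[key], abs=1e-8)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_compartments(list(zip(x, x))).r == pytest.approx(1.0)
        assert pearson_compartments(list(zip(x, -x))).r == pytest.approx(-1.0)

    def test_permutation_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        rs = []
        for _ in range(1000):
            perm = rng.permutation(y)
            rs.append(pearson_compartments(list(zip(x, perm))).r)
        assert abs(np.mean(rs)) < 0.03

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_compartments([(1.0, 1.0), (2.0, 2.0)])


def _long(rows):
    return pd.DataFrame(rows, columns=["patient_id", "image_id", "image_kind", "group", "metric", "value"])


class TestAggregate:
    def test_patient_mean_of_images(self):
        t = _long([
            ("p1", "i1", "single", "BNH", "m", 1.0),
            ("p1", "i2", "single", "BNH", "m", 1.2),
        ])
        out = aggregate(t, "patient")
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(1.1)

    def test_single_image_per_patient_is_identity(self):
        t = _long([("p1", "i1", "single", "BNH", "m", 2.5)])
        assert aggregate(t, "patient")["value"].iloc[0] == pytest.approx(2.5)

    def test_group_mean_is_mean_of_patient_means_not_image_pooling(self):
        # p1 has 3 images at 1.0; p2 has 1 image at 2.0
        t = _long([
            ("p1", "i1", "single", "BNH", "m", 1.0),
            ("p1", "i2", "single", "BNH", "m", 1.0),
            ("p1", "i3", "single", "BNH", "m", 1.0),
            ("p2", "i4", "single", "BNH", "m", 2.0),
        ])
        out = aggregate(t, "group")
        assert out["value"].iloc[0] == pytest.approx(1.5)  # (1.0 + 2.0)/2
        assert out["value"].iloc[0] != pytest.approx(t["value"].mean())  # 1.25 if pooled

    def test_aggregation_conserves_patient_count(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"p{i % 5}", f"i{i}", "single", "BNH", "m", float(rng.normal()))
            for i in range(17)
        ]
        out = aggregate(_long(rows), "patient")
        assert out["patient_id"].nunique() == 5

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            aggregate(_long([("p", "i", "single", "BNH", "m", 1.0)]), "slide")


class TestNarrowInterval:
    def test_example_subset(self):
        out = narrow_filter([1.00, 1.06, 1.08, 1.20])
        assert sorted(out) == [1.06, 1.08]

    def test_endpoints_inclusive_and_pure_subset(self):
        vals = [1.04999, 1.05, 1.07, 1.09, 1.09001]
        out = narrow_filter(vals)
        assert sorted(out) == [1.05, 1.07, 1.09]
        assert set(out) <= set(vals)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            narrow_filter([1.06], interval=(1.09, 1.05))


class TestFdFrequencyAnalysis:
    def test_all_inside_interval_narrowed_equals_full(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.uniform(1.05, 1.09, 30) for g in ("a", "b", "c")}
        hists, full, narrowed = fd_frequency_analysis(groups)
        assert narrowed is not None
        assert narrowed.f_stat == pytest.approx(full.f_stat, abs=1e-12)

    def test_histogram_counts_sum_to_inputs(self):
        rng = np.random.default_rng(9)
        groups = {"a": rng.uniform(1.0, 1.3, 40), "b": rng.uniform(1.0, 1.3, 25)}
        hists, _, _ = fd_frequency_analysis(groups)
        assert hists["a"].counts.sum() == 40
        assert hists["b"].counts.sum() == 25

    def test_group_without_narrowed_data_is_dropped_with_warning(self, caplog):
        groups = {
            "inside": [1.06, 1.07, 1.08, 1.06],
            "inside2": [1.055, 1.065, 1.075, 1.085],
            "outside": [1.4, 1.5, 1.6, 1.7],
        }
        with caplog.at_level("WARNING"):
            _, _, narrowed = fd_frequency_analysis(groups)
        assert "outside" in caplog.text
        assert narrowed is not None
        assert narrowed.df_between == 1  # two surviving groups
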