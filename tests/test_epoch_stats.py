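"""ANOVA, the studentized-range distribution, Tukey HSD and time binning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import whalebrain as wb
from whalebrain.epoch_stats import (
    EOCENE_BINS,
    TimeBin,
    studentized_range_cdf,
    f_sf,
)
from whalebrain.errors import DataError


class TestOneWayAnova:
    def test_identical_groups(self):
        res = wb.one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_separation_flagged(self):
        res = wb.one_way_anova([[0, 0], [1, 1]])
        assert math.isinf(res.f_statistic)
        assert res.p_value == 0.0
        assert res.exact_separation

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [rng.normal(i, 1.0, 4) for i in range(3)]
        res = wb.one_way_anova(groups)
        # brute-force decomposition
        allv = np.concatenate(groups)
        ssb = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 9)
        assert res.f_statistic == pytest.approx(f_oracle, abs=1e-10)
        ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_permutation_invariance(self, rng):
        groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 4), rng.normal(1, 1, 6)]
        a = wb.one_way_anova(groups)
        shuffled = [np.random.default_rng(1).permutation(g) for g in groups]
        b = wb.one_way_anova(list(reversed(shuffled)))
        assert a.f_statistic == pytest.approx(b.f_statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            wb.one_way_anova([[1.0, 2.0]])
        with pytest.raises(DataError):
            wb.one_way_anova([[1.0], [2.0]])

    def test_f_tail_via_incomplete_beta_matches_scipy(self):
        for f, d1, d2 in [(0.5, 2, 9), (3.2, 2, 8), (10.0, 4, 3)]:
            assert f_sf(f, d1, d2) == pytest.approx(
                stats.f.sf(f, d1, d2), rel=1e-10)


class TestStudentizedRange:
    @pytest.mark.parametrize("q,k,df", [
        (1.0, 2, 5), (3.5, 3, 10), (2.0, 4, 6), (5.0, 3, 4), (4.2, 5, 30),
    ])
    def test_cdf_matches_scipy(self, q, k, df):
        ref = stats.studentized_range.cdf(q, k, df)
        assert studentized_range_cdf(q, k, df) == pytest.approx(ref, abs=1e-6)

    def test_cdf_monotone_and_bounded(self):
        qs = np.linspace(0.1, 10, 25)
        vals = [studentized_range_cdf(q, 3, 8) for q in qs]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestTukeyHSD:
    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 5)
        res = wb.tukey_hsd([a, b])
        t = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.table.iloc[0]["q"] == pytest.approx(
            math.sqrt(2) * abs(t.statistic), rel=1e-10)
        assert res.table.iloc[0]["p_adjusted"] == pytest.approx(
            t.pvalue, abs=1e-4)

    def test_identical_groups_give_p_one(self):
        res = wb.tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (res.table["p_adjusted"] == 1.0).all()

    def test_unequal_sizes_match_scipy_tukey(self, rng):
        groups = [rng.normal(0, 1, 3), rng.normal(1, 1, 3), rng.normal(0.5, 1, 4)]
        ours = wb.tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups)
        for row_idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert ours.table.iloc[row_idx]["p_adjusted"] == pytest.approx(
                ref.pvalue[i, j], abs=1e-6)

    def test_adjusted_p_at_least_unadjusted_t_p(self, rng):
        """Conservativeness: each Tukey-adjusted p dominates the unadjusted
        pairwise t-test built on the same pooled error (MSW, n - k df)."""
        groups = [rng.normal(m, 1, 5) for m in (0.0, 0.4, 1.0)]
        res = wb.tukey_hsd(groups)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for row_idx, (i, j) in enumerate(pairs):
            diff = groups[i].mean() - groups[j].mean()
            se = math.sqrt(res.ms_within * (1 / len(groups[i]) + 1 / len(groups[j])))
            p_unadj = 2 * stats.t.sf(abs(diff) / se, res.df_within)
            assert res.table.iloc[row_idx]["p_adjusted"] >= p_unadj - 1e-10

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(DataError):
            wb.tukey_hsd([[1.0, 2.0]])

    def test_permutation_invariance(self, rng):
        groups = [rng.normal(m, 1, 4) for m in (0, 1, 2)]
        a = wb.tukey_hsd(groups, labels=list("XYZ"))
        b = wb.tukey_hsd(list(reversed(groups)), labels=list("ZYX"))
        pa = {frozenset((r["group_a"], r["group_b"])): r["p_adjusted"]
              for _, r in a.table.iterrows()}
        pb = {frozenset((r["group_a"], r["group_b"])): r["p_adjusted"]
              for _, r in b.table.iterrows()}
        for key in pa:
            assert pa[key] == pytest.approx(pb[key], rel=1e-10)


class TestTimeBins:
    def test_eocene_bin_membership_from_fossil_table(self, eocene_table,
                                                     registry):
        est = wb.build_fossil_estimates(eocene_table, registry)
        grouped = wb.assign_time_bins(est, EOCENE_BINS)
        middle = grouped["middle Eocene archaeocetes"]
        late = grouped["late Eocene basilosaurids"]
        assert set(middle.index) == {
            "Rodhocetus kasrani", "Dalanistes ahmedi",
            "Remingtonocetus harudiensis"}
        # 4 basilosaurid specimens collapse to 3 species values
        assert len(late) == 3
        assert "Zygorhiza kochii" in late.index

    def test_species_with_two_specimens_contributes_one_mean(self, eocene_table,
                                                             registry):
        est = wb.build_fossil_estimates(eocene_table, registry)
        grouped = wb.assign_time_bins(est, EOCENE_BINS)
        zygo = est[est["taxon"] == "Zygorhiza kochii"]["log10_EQ_0.56"]
        assert grouped["late Eocene basilosaurids"]["Zygorhiza kochii"] == \
            pytest.approx(zygo.mean())

    def test_age_window_bins(self):
        est = pd.DataFrame({
            "taxon": ["a", "b", "c"],
            "family": ["", "", ""],
            "age_ma": [40.0, 30.0, 25.0],
            "log10_EQ_0.56": [0.1, 0.2, 0.3],
        })
        bins = (TimeBin("Eocene", age_min=34.0, age_max=56.0),
                TimeBin("Oligocene", age_min=23.0, age_max=34.0))
        grouped = wb.assign_time_bins(est, bins)
        assert list(grouped["Eocene"].index) == ["a"]
        assert sorted(grouped["Oligocene"].index) == ["b", "c"]

    def test_empty_input_gives_empty_groups(self):
        est = pd.DataFrame(columns=["taxon", "family", "age_ma",
                                    "log10_EQ_0.56"])
        grouped = wb.assign_time_bins(est, EOCENE_BINS)
        assert all(len(v) == 0 for v in grouped.values())

    def test_compare_epochs_on_real_eocene_bins(self, eocene_table, registry):
        """Middle Eocene archaeocetes have lower log10 EQ than basilosaurids;
        the two-bin comparison should flag the separation clearly."""
        est = wb.build_fossil_estimates(eocene_table, registry)
        comp = wb.compare_epochs(est, EOCENE_BINS)
        means = dict(zip(comp.bin_names, comp.anova.group_means))
        assert means["middle Eocene archaeocetes"] < \
            means["late Eocene basilosaurids"]
        assert comp.anova.p_value < 0.05
        assert comp.tukey.table.iloc[0]["p_adjusted"] < 0.05
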