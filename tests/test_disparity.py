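"""Quintile/manual composition, SVI overlay, group comparison, top tracts."""

import numpy as np
import pandas as pd
import pytest

from cohaz.containers import RACE_GROUPS, TractTable, ValidationError
from cohaz.disparity import (
    DegenerateBinsError,
    compare_groups,
    manual_category_composition,
    quintile_composition,
    svi_overlay,
    top_tracts,
)
from conftest import planar_tract_table


def uniform_exposure_series(tracts, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.permutation(len(tracts)).astype(float) * 3,
                     index=tracts.tract_ids)


class TestQuintileComposition:
    def test_even_distribution_gives_twenty_percent(self):
        """When exposure is independent of composition every group puts
        ~20% of its population in each quintile (exactly 20% here since
        shares and populations are identical across tracts)."""
        tracts = planar_tract_table(n=5)   # 25 tracts, identical attributes
        e = uniform_exposure_series(tracts)
        comp = quintile_composition(e, tracts)
        for g in RACE_GROUPS:
            pcts = comp[comp["group"] == g]["percent"]
            np.testing.assert_allclose(pcts, 20.0)

    def test_concentrated_group_lands_in_top_quintile(self):
        tracts = planar_tract_table(n=4)
        df = tracts.data.copy()
        # one group lives only in the max-exposure tract
        df.loc[:, "nh_aian"] = 0.0
        df.loc[15, ["hispanic", "nh_white", "nh_black", "nh_asian",
                    "nh_other"]] = 0.0
        df.loc[15, "nh_aian"] = 1.0
        # renormalise the others
        others = df.index != 15
        cols = ["hispanic", "nh_white", "nh_black", "nh_asian", "nh_other"]
        df.loc[others, cols] = df.loc[others, cols].div(
            df.loc[others, cols].sum(axis=1), axis=0)
        tracts = TractTable(df, crs="planar")
        e = pd.Series(np.arange(16, dtype=float), index=tracts.tract_ids)
        comp = quintile_composition(e, tracts)
        aian_v = comp[(comp["group"] == "nh_aian") & (comp["category"] == "V")]
        assert float(aian_v["percent"].iloc[0]) == pytest.approx(100.0)

    def test_hand_computed_ten_tract_oracle(self):
        """Population-weighted composition on a 10-tract instance with
        hand-set shares equals the spreadsheet-style computation."""
        pops = [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]
        tracts = planar_tract_table(n=4, populations=pops + [0] * 6)
        df = tracts.data.copy()
        rng = np.random.default_rng(4)
        shares = rng.dirichlet(np.ones(6), size=16)
        df[RACE_GROUPS] = shares
        tracts = TractTable(df, crs="planar")
        e = pd.Series([5, 1, 8, 3, 9, 2, 7, 0, 6, 4] + [0] * 6,
                      index=tracts.tract_ids, dtype=float)
        comp = quintile_composition(e, tracts)
        # oracle: only populated tracts, breaks at 20/40/60/80 pct
        pop_ids = tracts.data.loc[tracts.data["population"] > 0,
                                  "tract_id"].tolist()
        e_pop = e[pop_ids]
        breaks = np.percentile(e_pop, [20, 40, 60, 80])
        labels = ["I", "II", "III", "IV", "V"]
        cat = {
            tid: labels[int(np.searchsorted(breaks, v, side="left"))]
            for tid, v in e_pop.items()
        }
        data = tracts.data.set_index("tract_id")
        for g in RACE_GROUPS:
            gp = {tid: data.loc[tid, "population"] * data.loc[tid, g]
                  for tid in pop_ids}
            total = sum(gp.values())
            for lab in labels:
                want = sum(v for t, v in gp.items() if cat[t] == lab) / total * 100
                got = comp[(comp["group"] == g) & (comp["category"] == lab)]
                assert float(got["percent"].iloc[0]) == pytest.approx(want)

    def test_percent_sums_to_hundred_per_group(self, bundle,
                                               recovery_tract_data):
        tracts = planar_tract_table(n=4)
        e = uniform_exposure_series(tracts, seed=3)
        comp = quintile_composition(e, tracts)
        sums = comp.groupby("group")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=0.1)

    def test_identical_exposures_degenerate(self):
        tracts = planar_tract_table(n=3)
        e = pd.Series(2.0, index=tracts.tract_ids)
        with pytest.raises(DegenerateBinsError, match="manual"):
            quintile_composition(e, tracts)

    def test_quintiles_hold_fifth_of_tracts(self):
        tracts = planar_tract_table(n=5)
        e = uniform_exposure_series(tracts, seed=8)   # distinct values
        comp = quintile_composition(e, tracts)
        # equal populations: percent per category ~ tract count per category
        pcts = comp[comp["group"] == "nh_white"].set_index("category")["percent"]
        assert (np.abs(pcts - 20.0) <= 100.0 / 25 + 1e-9).all()


class TestManualCategories:
    def test_all_zero_days_single_category(self):
        tracts = planar_tract_table(n=3)
        e = pd.Series(0.0, index=tracts.tract_ids)
        comp = manual_category_composition(e, tracts)
        zero = comp[comp["category"] == "0"]
        np.testing.assert_allclose(zero["percent"], 100.0)
        assert comp.groupby("group")["percent"].sum().pipe(
            np.allclose, 100.0)

    def test_default_edges_sum_to_hundred(self):
        tracts = planar_tract_table(n=4)
        rng = np.random.default_rng(0)
        e = pd.Series(rng.poisson(4, 16).astype(float), index=tracts.tract_ids)
        comp = manual_category_composition(e, tracts)
        sums = comp.groupby("group")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=0.1)

    def test_toy_assignment_matches_oracle(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series([0.0, 2.0, 5.0, 11.0], index=tracts.tract_ids)
        comp = manual_category_composition(e, tracts, edges=(0, 2, 5, 10))
        # equal pops and shares: each tract is 25% of every group
        for cat, want in [("0", 25.0), ("1-2", 25.0), ("3-5", 25.0),
                          ("6-10", 0.0), (">=11", 25.0)]:
            got = comp[(comp["group"] == "nh_white") & (comp["category"] == cat)]
            assert float(got["percent"].iloc[0]) == pytest.approx(want)

    def test_bad_edges_rejected(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series(1.0, index=tracts.tract_ids)
        with pytest.raises(ValidationError):
            manual_category_composition(e, tracts, edges=(0, 5, 5))
        with pytest.raises(ValidationError):
            manual_category_composition(e, tracts, edges=(1, 5))


class TestSviOverlay:
    def overlay_one(self, svi, e_days, cut=0.9):
        tracts = planar_tract_table(n=2)
        df = tracts.data.copy()
        df["svi"] = [svi, 0.1, 0.2, 0.3]
        tracts = TractTable(df, crs="planar")
        e = pd.Series([e_days, 0.0, 0.0, 0.0], index=tracts.tract_ids)
        flag, by_state, n_missing = svi_overlay(e, tracts, cut)
        return bool(flag.iloc[0])

    def test_vulnerable_but_unexposed_is_false(self):
        assert not self.overlay_one(svi=0.95, e_days=0)

    def test_vulnerable_and_exposed_is_true(self):
        assert self.overlay_one(svi=0.91, e_days=3)

    def test_cut_boundary_is_strict(self):
        assert not self.overlay_one(svi=0.90, e_days=3)

    def test_flagged_set_shrinks_as_cut_rises(self):
        tracts = planar_tract_table(n=4)
        rng = np.random.default_rng(5)
        e = pd.Series(rng.poisson(2, 16).astype(float), index=tracts.tract_ids)
        prev = None
        for cut in (0.5, 0.7, 0.9):
            flag, _, _ = svi_overlay(e, tracts, cut)
            if prev is not None:
                assert not (flag & ~prev).any()
            prev = flag

    def test_missing_svi_excluded_with_warning(self):
        tracts = planar_tract_table(n=2)
        df = tracts.data.copy()
        df.loc[0, "svi"] = np.nan
        tracts = TractTable.__new__(TractTable)  # bypass invariant check
        tracts.data = df
        tracts.crs = "planar"
        e = pd.Series(5.0, index=pd.Index(df["tract_id"]))
        with pytest.warns(UserWarning, match="lack SVI"):
            flag, _, n_missing = svi_overlay(e, tracts)
        assert n_missing == 1
        assert not flag.iloc[0]


class TestCompareGroups:
    def make(self, flagged_days, unflagged_days):
        n = 4
        tracts = planar_tract_table(n=n)
        df = tracts.data.copy()
        df["tribal_overlap"] = [i < 8 for i in range(16)]
        tracts = TractTable(df, crs="planar")
        e = pd.Series(
            flagged_days + unflagged_days, index=tracts.tract_ids, dtype=float
        )
        return tracts, e

    def test_identical_distributions_equal_means(self):
        tracts, e = self.make([3.0] * 8, [3.0] * 8)
        out = compare_groups(e, tracts, "tribal_overlap")
        assert out["mean_days"].iloc[0] == out["mean_days"].iloc[1] == 3.0

    def test_planted_difference_detected(self):
        tracts, e = self.make([10.0] * 8, [2.0] * 8)
        out = compare_groups(e, tracts, "tribal_overlap")
        flagged = out[out["tribal_overlap"]]["mean_days"].iloc[0]
        unflagged = out[~out["tribal_overlap"]]["mean_days"].iloc[0]
        assert flagged > unflagged

    def test_restriction_applied(self):
        tracts, e = self.make([10.0] * 8, [2.0] * 8)
        restrict = pd.Series([True] * 4 + [False] * 4 + [True] * 8,
                             index=e.index)
        out = compare_groups(e, tracts, "tribal_overlap", restrict=restrict)
        assert out[out["tribal_overlap"]]["n_tracts"].iloc[0] == 4

    def test_empty_side_rejected(self):
        tracts, e = self.make([1.0] * 8, [1.0] * 8)
        restrict = pd.Series([True] * 8 + [False] * 8, index=e.index)
        with pytest.raises(ValidationError, match="no tracts"):
            compare_groups(e, tracts, "tribal_overlap", restrict=restrict)


class TestTopTracts:
    def test_sorted_descending_with_cohort_average(self):
        tracts = planar_tract_table(n=4)
        rng = np.random.default_rng(11)
        e = pd.Series(rng.permutation(16).astype(float), index=tracts.tract_ids)
        top = top_tracts(e, tracts, n=5)
        assert list(top["days"]) == sorted(e, reverse=True)[:5]
        assert top["cohort_avg_days"].iloc[0] == pytest.approx(e.mean())
        assert set(top.columns) >= {
            "tract_id", "state", "pct_65plus", "pct_disability",
            "nonwhite_pct", "pct_poverty150", "days", "cohort_avg_days",
        }

    def test_ties_broken_by_tract_id(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series([5.0, 5.0, 5.0, 1.0], index=tracts.tract_ids)
        top = top_tracts(e, tracts, n=3)
        assert list(top["tract_id"]) == sorted(tracts.tract_ids[:3])

    def test_n_larger_than_tract_count_returns_all(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series([1.0, 2.0, 3.0, 4.0], index=tracts.tract_ids)
        assert len(top_tracts(e, tracts, n=100)) == 4

    def test_all_zero_exposure(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series(0.0, index=tracts.tract_ids)
        top = top_tracts(e, tracts, n=2)
        assert (top["days"] == 0).all()
        assert (top["cohort_avg_days"] == 0).all()

    def test_nonwhite_percent_complements_nh_white(self):
        tracts = planar_tract_table(n=2)
        e = pd.Series([4.0, 3.0, 2.0, 1.0], index=tracts.tract_ids)
        top = top_tracts(e, tracts, n=1)
        assert top["nonwhite_pct"].iloc[0] == pytest.approx(50.0)
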