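import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphnet.enrichment import (
    ContingencyTable2x2,
    co_enrich,
    enrich,
    fisher_exact_two_sided,
    hypergeom_tail,
    odds_ratio,
    relative_risk,
)
from morphnet.errors import StatsError


# ---------------------------------------------------------------- oracles
def tail_by_combination_enumeration(k, n, K, N):
    """P(X >= k) by explicit enumeration of all C(N, n) draws."""
    items = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(items, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return Fraction(hits, total)


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Exact two-sided p over all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    total = comb(n, col1)
    probs = [
        Fraction(comb(row1, x) * comb(n - row1, col1 - x), total)
        for x in range(lo, hi + 1)
    ]
    observed = probs[a - lo]
    return sum(p for p in probs if p <= observed)


# ---------------------------------------------------------------- hypergeom
class TestHypergeomTail:
    def test_worked_value_1_over_15504(self):
        assert hypergeom_tail(5, 5, 5, 20) == pytest.approx(1 / 15504, abs=1e-15)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 5, 3, 20) == 1.0

    def test_certain_event(self):
        assert hypergeom_tail(7, 7, 7, 7) == 1.0

    @pytest.mark.parametrize("args", [(6, 5, 5, 20), (3, 5, 25, 20), (1, 25, 5, 20), (-1, 5, 5, 20)])
    def test_bounds(self, args):
        with pytest.raises(StatsError):
            hypergeom_tail(*args)

    def test_matches_combination_enumeration(self):
        # literal draw-enumeration oracle, small N
        for N, n, K in [(8, 3, 4), (9, 4, 5), (10, 5, 3), (11, 4, 6)]:
            for k in range(0, n + 1):
                expected = float(tail_by_combination_enumeration(k, n, K, N))
                assert hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-14)

    def test_matches_scipy_up_to_N30(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            N = int(rng.integers(2, 31))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, n + 1))
            expected = stats.hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- enrich
def annotations_frame(labels_by_scan):
    frame = pd.DataFrame.from_dict(labels_by_scan, orient="index")
    frame.index.name = "scan_id"
    return frame


class TestEnrich:
    def _simple(self):
        scans = [f"s{i:02d}" for i in range(20)]
        colours = {s: {"colour": "red" if i < 5 else "blue"} for i, s in enumerate(scans)}
        return scans, annotations_frame(colours)

    def test_whole_population_group_never_significant(self):
        scans, ann = self._simple()
        table = enrich({"all": scans}, ann)
        assert (table["p_value"] == 1.0).all()

    def test_perfect_cluster_matches_worked_value(self):
        scans, ann = self._simple()
        table = enrich({"c1": scans[:5]}, ann)
        row = table[(table["descriptor"] == "red")].iloc[0]
        assert row["p_value"] == pytest.approx(1 / 15504, abs=1e-15)
        assert row["observed"] == 5 and row["descriptor_total"] == 5
        assert row["expected"] == pytest.approx(5 * 5 / 20)
        assert bool(row["reported"]) is True

    def test_low_observed_rows_kept_but_unreported(self):
        scans, ann = self._simple()
        table = enrich({"c1": scans[3:7]}, ann)  # 2 red members
        row = table[table["descriptor"] == "red"].iloc[0]
        assert row["observed"] == 2
        assert bool(row["reported"]) is False

    def test_empty_group_skipped_with_warning(self):
        scans, ann = self._simple()
        with pytest.warns(UserWarning, match="empty"):
            table = enrich({"c1": scans[:5], "ghost": ["nope"]}, ann)
        assert set(table["group_label"]) == {"c1"}

    def test_missing_annotations_shrink_population(self):
        scans, ann = self._simple()
        ann.loc["s10":"s19", "colour"] = None
        table = enrich({"c1": scans[:5]}, ann)
        assert (table["population"] == 10).all()

    def test_p_values_match_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        scans = [f"s{i:02d}" for i in range(12)]
        for _ in range(20):
            labels = {s: {"cat": rng.choice(["x", "y", "z"])} for s in scans}
            ann = annotations_frame(labels)
            group = list(rng.choice(scans, size=5, replace=False))
            table = enrich({"g": group}, ann)
            for _, row in table.iterrows():
                expected = tail_by_combination_enumeration(
                    int(row["observed"]),
                    int(row["group_size"]),
                    int(row["descriptor_total"]),
                    int(row["population"]),
                )
                assert row["p_value"] == pytest.approx(float(expected), abs=1e-12)

    def test_adjustment_monotone_and_rank_preserving(self):
        rng = np.random.default_rng(4)
        scans = [f"s{i:02d}" for i in range(30)]
        ann = annotations_frame(
            {s: {"cat": rng.choice(list("abcd"))} for s in scans}
        )
        groups = {f"g{j}": list(rng.choice(scans, size=8, replace=False)) for j in range(4)}
        for method in ("bh", "bonferroni"):
            table = enrich(groups, ann, adjust_method=method)
            assert (table["adjusted_p"] >= table["p_value"] - 1e-15).all()
            ranked = table.sort_values("p_value")
            assert ranked["adjusted_p"].is_monotonic_increasing

    def test_unknown_adjustment_rejected(self):
        scans, ann = self._simple()
        with pytest.raises(StatsError):
            enrich({"c1": scans[:5]}, ann, adjust_method="holm-sidak")


class TestCoEnrich:
    def _ann(self):
        scans = [f"s{i:02d}" for i in range(20)]
        rows = {}
        for i, s in enumerate(scans):
            rows[s] = {
                "breed": "boxer" if i < 4 else "lab",
                "age": "old" if i in (0, 1, 2, 10) else "young",
            }
        return scans, annotations_frame(rows)

    def test_empty_intersection_gives_p_one(self):
        scans, ann = self._ann()
        table = co_enrich({"g": scans[4:8]}, ann, ("breed", "age"))
        row = table[table["descriptor"] == "boxer & old"].iloc[0]
        assert row["observed"] == 0 and row["p_value"] == 1.0

    def test_degenerate_pair_equals_single_category(self):
        scans = [f"s{i:02d}" for i in range(10)]
        ann = annotations_frame(
            {s: {"a": "x" if i < 4 else "y", "b": "only"} for i, s in enumerate(scans)}
        )
        single = enrich({"g": scans[:4]}, ann, categories=["a"])
        joint = co_enrich({"g": scans[:4]}, ann, ("a", "b"))
        row_s = single[single["descriptor"] == "x"].iloc[0]
        row_j = joint[joint["descriptor"] == "x & only"].iloc[0]
        for col in ("observed", "descriptor_total", "population", "p_value"):
            assert row_j[col] == row_s[col]

    def test_derived_three_of_four(self):
        scans, ann = self._ann()
        # boxer & old covers s00..s02 -> K=3; group holds all three plus s10
        group = ["s00", "s01", "s02", "s10"]
        table = co_enrich({"g": group}, ann, ("breed", "age"))
        row = table[table["descriptor"] == "boxer & old"].iloc[0]
        expected = tail_by_combination_enumeration(3, 4, 3, 20)
        assert row["observed"] == 3
        assert row["p_value"] == pytest.approx(float(expected), abs=1e-14)

    def test_unknown_category_rejected(self):
        scans, ann = self._ann()
        with pytest.raises(StatsError):
            co_enrich({"g": scans[:4]}, ann, ("breed", "missing"))


# ---------------------------------------------------------------- 2x2 risk
class TestOddsRatio:
    def test_symmetric_table(self):
        res = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.corrected is False

    def test_zero_cells_haldane_correction(self):
        res = odds_ratio(ContingencyTable2x2(2, 0, 0, 2))
        assert res.corrected is True
        assert res.odds_ratio == pytest.approx((2.5 * 2.5) / (0.5 * 0.5))
        assert res.p_value == pytest.approx(1 / 3, abs=1e-15)  # enumeration: C(4,2)=6 tables

    def test_derived_1_9_11_3(self):
        res = odds_ratio(ContingencyTable2x2(1, 9, 11, 3))
        expected = fisher_two_sided_by_enumeration(1, 9, 11, 3)
        assert res.p_value == pytest.approx(float(expected), abs=1e-14)

    def test_two_sided_p_matches_enumeration_margins_up_to_20(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            t = ContingencyTable2x2(a, b, c, d)
            try:
                res = odds_ratio(t)
            except StatsError:
                continue  # zero margin
            expected = fisher_two_sided_by_enumeration(a, b, c, d)
            assert res.p_value == pytest.approx(float(expected), abs=1e-12)

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(1, 15, size=4))
            res = odds_ratio(ContingencyTable2x2(a, b, c, d))
            expected = stats.fisher_exact([[a, b], [c, d]])[1]
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_row_and_column_swap_invariance(self):
        res = odds_ratio(ContingencyTable2x2(3, 7, 5, 9))
        swapped = odds_ratio(ContingencyTable2x2(9, 5, 7, 3))
        assert swapped.odds_ratio == pytest.approx(res.odds_ratio)
        assert swapped.p_value == pytest.approx(res.p_value)

    def test_row_swap_inverts_or(self):
        res = odds_ratio(ContingencyTable2x2(3, 7, 5, 9))
        flipped = odds_ratio(ContingencyTable2x2(5, 9, 3, 7))
        assert flipped.odds_ratio == pytest.approx(1 / res.odds_ratio)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            odds_ratio(ContingencyTable2x2(0, 0, 5, 5))
        with pytest.raises(StatsError):
            odds_ratio(ContingencyTable2x2(0, 5, 0, 5))

    def test_woolf_ci_brackets_estimate(self):
        res = odds_ratio(ContingencyTable2x2(8, 2, 3, 9))
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_conditional_exact_ci(self):
        res = odds_ratio(ContingencyTable2x2(8, 2, 3, 9), ci_method="conditional-exact")
        assert res.ci_low < res.ci_high
        assert res.ci_method == "conditional-exact"

    def test_unknown_ci_method(self):
        with pytest.raises(StatsError):
            odds_ratio(ContingencyTable2x2(1, 1, 1, 1), ci_method="bayes")

    def test_invalid_cells(self):
        with pytest.raises(StatsError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(StatsError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "cells,expected",
        [((10, 10, 10, 10), 1.0), ((2, 8, 1, 9), 2.0), ((0, 10, 5, 5), 0.0)],
    )
    def test_values(self, cells, expected):
        assert relative_risk(ContingencyTable2x2(*cells)) == pytest.approx(expected)

    def test_zero_baseline_risk_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert relative_risk(ContingencyTable2x2(3, 7, 0, 10)) == float("inf")

    def test_empty_row_rejected(self):
        with pytest.raises(StatsError):
            relative_risk(ContingencyTable2x2(0, 0, 5, 5))


def test_fisher_two_sided_direct():
    assert fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(1 / 3, abs=1e-15)
    assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)
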