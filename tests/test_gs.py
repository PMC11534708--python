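"""Goods-and-services costing: monthly equivalents, summaries, affordability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discost import (
    CostAggregator,
    CostItem,
    affordability_percentile,
    monthly_equivalent,
    person_monthly_cost,
    summarize_costs,
    wage_gap,
)
from discost.domains import GS_CATEGORIES


class TestMonthlyEquivalent:
    def test_straight_line_amortization(self):
        item = CostItem(1, "wheelchair", "assistive_devices", 120_000, 12)
        assert monthly_equivalent(item) == pytest.approx(10_000)

    def test_annual_spend_as_twelve_month_lifespan(self):
        # an annual 50k device budget expressed with a 12-month lifespan
        item = CostItem(1, "cane", "assistive_devices", 50_000, 12)
        assert monthly_equivalent(item) == pytest.approx(4_166.67, abs=0.01)

    def test_recurring_frequency(self):
        item = CostItem(1, "taxi", "commute_travel", 0, 0, 10_000, 13)
        assert monthly_equivalent(item) == pytest.approx(130_000)

    def test_one_off_mode_counts_full_price(self):
        item = CostItem(1, "wheelchair", "assistive_devices", 120_000, 12)
        assert monthly_equivalent(item, amortization="one_off") == 120_000

    def test_invalid_items_rejected(self):
        with pytest.raises(ValueError):
            CostItem(1, "x", "magic_category")
        with pytest.raises(ValueError):
            CostItem(1, "x", "essential_needs", purchase_price=-5)


def _random_items(n=200, seed=9):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "respondent_id": rng.integers(0, 30, n),
            "item": "thing",
            "category": rng.choice(GS_CATEGORIES, n),
            "purchase_price": rng.uniform(0, 1e6, n),
            "lifespan_months": rng.choice([0, 6, 12, 60], n).astype(float),
            "recurring_cost": rng.uniform(0, 1e5, n),
            "frequency_per_month": rng.choice([0, 1, 4, 30], n).astype(float),
            "disability_specific": rng.random(n) < 0.7,
        }
    )


class TestPersonMonthlyCost:
    def test_empty_items(self):
        out = person_monthly_cost(_random_items(0))
        assert out.empty

    def test_category_additivity(self):
        items = pd.DataFrame(
            {
                "respondent_id": 1,
                "item": list(GS_CATEGORIES),
                "category": list(GS_CATEGORIES),
                "purchase_price": 60_000.0,
                "lifespan_months": 12.0,
                "recurring_cost": 0.0,
                "frequency_per_month": 0.0,
                "disability_specific": True,
            }
        )
        out = person_monthly_cost(items)
        assert out.loc[1, "total"] == pytest.approx(6 * 5_000)
        assert out.loc[1, "total"] == pytest.approx(out.loc[1, list(GS_CATEGORIES)].sum())

    def test_matches_bruteforce_summation(self):
        items = _random_items()
        out = person_monthly_cost(items)
        for rid, grp in items.groupby("respondent_id"):
            expect = sum(
                monthly_equivalent(
                    CostItem(
                        rid,
                        r.item,
                        r.category,
                        r.purchase_price,
                        r.lifespan_months,
                        r.recurring_cost,
                        r.frequency_per_month,
                        r.disability_specific,
                    )
                )
                for r in grp.itertuples()
            )
            assert out.loc[rid, "total"] == pytest.approx(expect)
            extra = sum(
                monthly_equivalent(CostItem(rid, r.item, r.category, r.purchase_price,
                                            r.lifespan_months, r.recurring_cost,
                                            r.frequency_per_month))
                for r in grp.itertuples()
                if r.disability_specific
            )
            assert out.loc[rid, "disability_extra"] == pytest.approx(extra)


class TestSummaries:
    def test_declared_quantile_method_on_small_fixture(self):
        totals = pd.DataFrame({"disability_type": "seeing", "total": [1.0, 2.0, 3.0, 4.0]})
        out = summarize_costs(totals).set_index("disability_type")
        assert out.loc["seeing", "median"] == 2.5
        assert out.loc["seeing", "mean"] == 2.5
        assert out.loc["seeing", "p75"] == 3.25

    def test_constant_totals(self):
        totals = pd.DataFrame({"disability_type": "seeing", "total": [7.0] * 5})
        row = summarize_costs(totals).set_index("disability_type").loc["seeing"]
        assert row["median"] == row["mean"] == row["p75"] == 7.0

    def test_group_medians_match_sort_and_pick_oracle(self):
        rng = np.random.default_rng(2)
        totals = pd.DataFrame(
            {
                "disability_type": rng.choice(["seeing", "hearing", "multiple"], 150),
                "total": rng.lognormal(14, 0.8, 150),
            }
        )
        out = summarize_costs(totals).set_index("disability_type")
        for g, grp in totals.groupby("disability_type"):
            v = np.sort(grp["total"].to_numpy())
            assert out.loc[g, "median"] == pytest.approx(np.quantile(v, 0.5))
            assert out.loc[g, "p75"] == pytest.approx(np.quantile(v, 0.75))
            assert out.loc[g, "median"] <= out.loc[g, "p75"]
        assert out.loc["overall", "n"] == 150

    def test_scaling_all_prices_scales_every_statistic(self):
        items = _random_items()
        s1 = summarize_costs(
            person_monthly_cost(items).reset_index().assign(disability_type="all")
        )
        scaled = items.copy()
        for c in ("purchase_price", "recurring_cost"):
            scaled[c] *= 3.0
        s2 = summarize_costs(
            person_monthly_cost(scaled).reset_index().assign(disability_type="all")
        )
        for stat in ("median", "mean", "p75"):
            assert s2[stat].to_numpy() == pytest.approx(3.0 * s1[stat].to_numpy())


class TestWageGap:
    def test_gap_ratio_and_strict_flag(self):
        summary = pd.DataFrame(
            [{"disability_type": "seeing", "median": 2_000_000.0, "mean": 2_000_000.0, "p75": 2_000_000.0, "n": 5}]
        )
        out = wage_gap(summary, 1_800_000).iloc[0]
        assert out["median_gap"] == pytest.approx(200_000)
        assert out["median_ratio"] == pytest.approx(1.11, abs=0.01)
        assert bool(out["median_exceeds_wage"])
        boundary = wage_gap(summary.assign(median=1_800_000.0), 1_800_000).iloc[0]
        assert not bool(boundary["median_exceeds_wage"])  # strict exceedance

    def test_median_below_mean_p75_above_pattern(self):
        summary = pd.DataFrame(
            [{"disability_type": "x", "median": 1_500_000.0, "mean": 2_100_000.0, "p75": 2_600_000.0, "n": 9}]
        )
        out = wage_gap(summary, 1_800_000).iloc[0]
        assert [bool(out[f"{s}_exceeds_wage"]) for s in ("median", "mean", "p75")] == [
            False,
            True,
            True,
        ]


class TestAffordability:
    def test_bounds(self):
        x = np.array([2.0, 3.0, 5.0])
        assert affordability_percentile(1.0, x) == 0.0
        assert affordability_percentile(5.0, x) == 100.0

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_cost(self, a, b):
        x = np.linspace(0.5, 8.0, 50)
        lo, hi = sorted((a, b))
        assert affordability_percentile(lo, x) <= affordability_percentile(hi, x)

    def test_weighted_ecdf(self):
        x = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, 1.0, 2.0])
        assert affordability_percentile(2.0, x, w) == pytest.approx(50.0)


def test_aggregator_keeps_item_free_respondents():
    items = _random_items(50)
    respondents = pd.DataFrame(
        {"respondent_id": range(40), "disability_type": ["seeing"] * 20 + ["none"] * 20}
    )
    agg = CostAggregator().fit(items, respondents)
    assert len(agg.person_totals_) == 40
    assert (agg.person_totals_["total"] >= 0).all()
    summary = agg.summarize()
    assert "overall" in set(summary["disability_type"])
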