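"""Goods-and-services (GS) costing: monthly equivalents, summaries, affordability.

Cost drivers reported by respondents fall into six categories (assistive
devices, special accommodation, human assistance, commute travel,
interstate travel, essential needs). Each item is converted to a monthly
equivalent: durable purchases are amortized straight-line over their
lifespan in months, non-durables count their price once per month, and
recurring unit costs are multiplied by monthly frequency. Per-person
totals are summarized as median / mean / 75th percentile by disability
type, overall, and optionally by age band, then assessed against a
minimum-wage floor and a per-capita expenditure distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .domains import GS_CATEGORIES

ITEM_COLUMNS = (
    "respondent_id",
    "item",
    "category",
    "purchase_price",
    "lifespan_months",
    "recurring_cost",
    "frequency_per_month",
    "disability_specific",
)


@dataclass(frozen=True)
class CostItem:
    """One cost-driver record for one respondent."""

    respondent_id: object
    item: str
    category: str
    purchase_price: float = 0.0
    lifespan_months: float = 0.0  # 0 => non-durable
    recurring_cost: float = 0.0
    frequency_per_month: float = 0.0
    disability_specific: bool = True

    def __post_init__(self):
        if self.category not in GS_CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        if self.lifespan_months < 0 or self.frequency_per_month < 0:
            raise ValueError("lifespan and frequency must be non-negative")
        if self.purchase_price < 0 or self.recurring_cost < 0:
            raise ValueError("prices must be non-negative")


def monthly_equivalent(item: CostItem | pd.Series, amortization: str = "straight_line") -> float:
    """Monthly-equivalent cost of one item, in currency units per month.

    Durables (lifespan > 0) are spread uniformly over their lifespan;
    non-durables (lifespan 0) count the full purchase price in the month
    of purchase (``amortization="one_off"`` counts durables the same way).
    Recurring unit costs are added at their monthly frequency.
    """
    price = float(item.purchase_price if isinstance(item, CostItem) else item["purchase_price"])
    life = float(item.lifespan_months if isinstance(item, CostItem) else item["lifespan_months"])
    rec = float(item.recurring_cost if isinstance(item, CostItem) else item["recurring_cost"])
    freq = float(
        item.frequency_per_month if isinstance(item, CostItem) else item["frequency_per_month"]
    )
    if price < 0 or rec < 0 or life < 0 or freq < 0:
        raise ValueError("cost components must be non-negative")
    if life > 0 and amortization == "straight_line":
        base = price / life
    else:
        base = price
    return base + rec * freq


def monthly_equivalents(items: pd.DataFrame, amortization: str = "straight_line") -> pd.Series:
    """Vectorised :func:`monthly_equivalent` over an item table."""
    price = items["purchase_price"].to_numpy(float)
    life = items["lifespan_months"].to_numpy(float)
    rec = items["recurring_cost"].to_numpy(float)
    freq = items["frequency_per_month"].to_numpy(float)
    if (price < 0).any() or (rec < 0).any() or (life < 0).any() or (freq < 0).any():
        raise ValueError("cost components must be non-negative")
    bad = ~items["category"].isin(GS_CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown cost categories: {sorted(items.loc[bad, 'category'].unique())}")
    if amortization == "straight_line":
        base = np.where(life > 0, price / np.where(life > 0, life, 1.0), price)
    elif amortization == "one_off":
        base = price
    else:
        raise ValueError(f"unknown amortization mode {amortization!r}")
    return pd.Series(base + rec * freq, index=items.index, name="monthly_cost")


def person_monthly_cost(items: pd.DataFrame, amortization: str = "straight_line") -> pd.DataFrame:
    """Per-respondent monthly cost by category, total, and disability-specific total.

    Returns one row per respondent with one column per GS category, a
    ``total`` column (sum over categories) and ``disability_extra`` (total
    over disability-specific items only). Respondents with no items are
    absent; upstream code reindexes with zeros where needed.
    """
    if items.empty:
        cols = list(GS_CATEGORIES) + ["total", "disability_extra"]
        return pd.DataFrame(columns=cols).rename_axis("respondent_id")
    df = items.copy()
    df["monthly_cost"] = monthly_equivalents(df, amortization)
    by_cat = (
        df.pivot_table(
            index="respondent_id",
            columns="category",
            values="monthly_cost",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(GS_CATEGORIES), fill_value=0.0)
    )
    by_cat.columns.name = None
    by_cat["total"] = by_cat[list(GS_CATEGORIES)].sum(axis=1)
    extra = (
        df[df["disability_specific"].astype(bool)]
        .groupby("respondent_id")["monthly_cost"]
        .sum()
        .reindex(by_cat.index, fill_value=0.0)
    )
    by_cat["disability_extra"] = extra
    return by_cat


def quantile_linear(values, q: float) -> float:
    """Linear-interpolation quantile between order statistics (numpy default)."""
    return float(np.quantile(np.asarray(values, float), q, method="linear"))


def summarize_costs(
    totals: pd.DataFrame,
    group_col: str = "disability_type",
    value_col: str = "total",
    age_band_col: str | None = None,
) -> pd.DataFrame:
    """Median / mean / P75 monthly cost by group (and 'overall'), optionally by age band.

    ``totals`` has one row per respondent. The median is read as the lower
    end of the cost of disability, the mean as the middle, P75 as the
    higher end. Empty groups are omitted with a warning.
    """
    if totals.empty:
        raise ValueError("no respondents to summarize")
    frames = [totals.assign(**{group_col: "overall"}), totals]
    rows = []
    for frame in frames:
        keys = [group_col] + ([age_band_col] if age_band_col else [])
        for key, sub in frame.groupby(keys, sort=True, observed=True):
            key = key if isinstance(key, tuple) else (key,)
            if sub.empty:
                warnings.warn(f"empty group {key}; omitted")
                continue
            v = sub[value_col].to_numpy(float)
            row = {
                group_col: key[0],
                "median": quantile_linear(v, 0.5),
                "mean": float(v.mean()),
                "p75": quantile_linear(v, 0.75),
                "n": int(len(v)),
            }
            if age_band_col:
                row[age_band_col] = key[1]
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.drop_duplicates(subset=[c for c in out.columns if c not in ("median", "mean", "p75", "n")]).reset_index(drop=True)


def wage_gap(summary: pd.DataFrame, minimum_wage: float) -> pd.DataFrame:
    """Compare cost statistics to a monthly minimum wage.

    Adds, per statistic in {median, mean, p75}: the gap (cost - wage), the
    cost/wage ratio, and an exceedance flag (strict: a cost exactly at the
    wage does not flag).
    """
    if minimum_wage <= 0:
        raise ValueError("minimum wage must be positive")
    out = summary.copy()
    for stat in ("median", "mean", "p75"):
        out[f"{stat}_gap"] = out[stat] - minimum_wage
        out[f"{stat}_ratio"] = out[stat] / minimum_wage
        out[f"{stat}_exceeds_wage"] = out[stat] > minimum_wage
    return out


def affordability_percentile(cost: float, expenditures, weights=None) -> float:
    """Position of a monthly cost in the per-capita expenditure distribution.

    Returns 100 * F(cost) where F is the weighted ECDF
    (P[expenditure <= cost]); only persons above this percentile out-spend
    the cost. Non-decreasing in cost; 0 below the sample minimum, 100 at
    or above the maximum.
    """
    x = np.asarray(expenditures, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one expenditure observation")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    return float(100.0 * w[x <= cost].sum() / w.sum())


class CostAggregator(BaseEstimator):
    """Estimator turning a cost-item table into per-person totals and summaries.

    Parameters
    ----------
    amortization : {"straight_line", "one_off"}
        Durable-purchase treatment in the monthly equivalent.
    """

    def __init__(self, amortization: str = "straight_line"):
        self.amortization = amortization

    def fit(self, items: pd.DataFrame, respondents: pd.DataFrame | None = None):
        """Compute per-person totals; ``respondents`` (respondent_id,
        disability_type, optional age) attaches grouping keys, with
        item-free respondents kept at zero cost."""
        totals = person_monthly_cost(items, self.amortization)
        if respondents is not None:
            meta = respondents.set_index("respondent_id")
            totals = totals.reindex(meta.index, fill_value=0.0)
            for col in meta.columns:
                totals[col] = meta[col]
        self.person_totals_ = totals.reset_index()
        return self

    def summarize(self, group_col: str = "disability_type", age_band_col: str | None = None) -> pd.DataFrame:
        return summarize_costs(self.person_totals_, group_col=group_col, age_band_col=age_band_col)

    def wage_gap(self, minimum_wage: float, **kw) -> pd.DataFrame:
        return wage_gap(self.summarize(**kw), minimum_wage)
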