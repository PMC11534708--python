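"""Poverty-line adjustment for disability extra costs and headcount ratios.

The official per-capita poverty line understates the needs of households
facing disability-related extra costs. Scaling each disability household's
line by (1 + m), with m the relevant extra-cost multiplier, yields an
adjusted headcount. The selection rule follows the bottom-40% convention:
single-type households take their type's bottom-40% multiplier; households
with several disability types take the highest multiplier among their
types; blank (non-significant) cells default to zero, which is the
conservative choice (it understates adjusted poverty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .domains import DOMAINS
from .sol import BOTTOM40, MultiplierTable


@dataclass(frozen=True)
class MultiplierPolicy:
    """How household multipliers are read off the multiplier table.

    source : "bottom40_pooled" (one multiplier per type, from the pooled
        Q1+Q2 stratum) or "per_quintile" (the household's own quintile cell).
    multiple_rule : "max_over_types" — a multi-type household takes the
        highest multiplier among its flagged types.
    blank_rule : "treat_as_zero" or "exclude_household" for BLANK cells.
    """

    source: str = "bottom40_pooled"
    multiple_rule: str = "max_over_types"
    blank_rule: str = "treat_as_zero"

    def __post_init__(self):
        if self.source not in ("bottom40_pooled", "per_quintile"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.multiple_rule != "max_over_types":
            raise ValueError(f"unknown multiple_rule {self.multiple_rule!r}")
        if self.blank_rule not in ("treat_as_zero", "exclude_household"):
            raise ValueError(f"unknown blank_rule {self.blank_rule!r}")


def household_multiplier(
    flags: dict[str, bool] | pd.Series,
    table: MultiplierTable,
    policy: MultiplierPolicy = MultiplierPolicy(),
    threshold: str = "higher",
    quintile=None,
) -> float | None:
    """Extra-cost multiplier (a fraction, e.g. 0.083) for one household.

    ``flags`` maps domain name -> bool. No flagged type gives 0. Each
    flagged type contributes its table cell (bottom-40% pooled row, or the
    household's own ``quintile`` under the per-quintile source); a
    multi-type household takes the maximum. Returns None when
    ``blank_rule="exclude_household"`` and every flagged type is blank.
    Raises KeyError when a flagged type has no row in the table at all.
    """
    flagged = [d for d in DOMAINS if bool(flags.get(d, False) if isinstance(flags, dict) else flags[d])]
    if not flagged:
        return 0.0
    q = BOTTOM40 if policy.source == "bottom40_pooled" else quintile
    if q is None:
        raise ValueError("per_quintile policy needs the household's quintile")
    ql = MultiplierTable.quintile_label(q)
    present = set(
        table.df.loc[
            (table.df["quintile"] == ql) & (table.df["threshold"] == threshold), "type"
        ]
    )
    values = []
    for d in flagged:
        if d not in present:
            raise KeyError(f"multiplier table has no {d}/{ql}/{threshold} row")
        cell = table.cell(d, q, threshold)
        if cell is None:
            if policy.blank_rule == "treat_as_zero":
                values.append(0.0)
            # exclude_household: contribute nothing
        else:
            values.append(cell / 100.0)
    if not values:
        return None  # all flagged cells blank under exclude_household
    return float(max(values))


def adjusted_line(line: float, m: float) -> float:
    """Poverty line scaled for extra costs: line * (1 + m)."""
    line = np.asarray(line, dtype=float)
    m = np.asarray(m, dtype=float)
    if (line <= 0).any():
        raise ValueError("poverty line must be positive")
    if (m < 0).any():
        raise ValueError("multiplier must be non-negative")
    out = line * (1.0 + m)
    return float(out) if out.ndim == 0 else out


@dataclass
class PovertyResult:
    """Headcount rates for one disability group."""

    group: str
    n_households: float
    unadjusted_rate: float
    adjusted_rate: float
    n_poor_unadjusted: float
    n_poor_adjusted: float


def poverty_headcount(
    households: pd.DataFrame,
    use_adjusted: bool = True,
    weight_col: str | None = None,
) -> pd.DataFrame:
    """Weighted poverty headcount rates by disability group.

    Requires ``exp_pc``, ``poverty_line``, ``multiplier`` (fraction; NaN
    marks households excluded under the exclude_household blank rule) and
    the ``hh_disabled_lower`` / ``hh_disabled_higher`` flags. A household
    is poor when exp_pc < line (unadjusted) or exp_pc < line*(1+m)
    (adjusted). Groups: no disability (not flagged at the lower threshold),
    any-difficulty households (lower threshold), and their moderate/severe
    subset (higher threshold).
    """
    for col in ("exp_pc", "poverty_line", "multiplier"):
        if col not in households.columns:
            raise ValueError(f"missing column {col!r}")
    if households["poverty_line"].isna().any():
        raise ValueError("missing poverty line")
    df = households[~households["multiplier"].isna()] if use_adjusted else households
    w = np.ones(len(df)) if weight_col is None else df[weight_col].to_numpy(float)
    exp_pc = df["exp_pc"].to_numpy(float)
    line = df["poverty_line"].to_numpy(float)
    m = df["multiplier"].to_numpy(float)
    poor_un = exp_pc < line
    poor_adj = exp_pc < line * (1.0 + m)
    groups = {
        "no_disability": ~df["hh_disabled_lower"].to_numpy(bool),
        "disability_lower": df["hh_disabled_lower"].to_numpy(bool),
        "disability_higher": df["hh_disabled_higher"].to_numpy(bool),
    }
    rows = []
    for name, sel in groups.items():
        wt = w[sel].sum()
        nu = float((w[sel] * poor_un[sel]).sum())
        na = float((w[sel] * poor_adj[sel]).sum()) if use_adjusted else nu
        rows.append(
            PovertyResult(
                group=name,
                n_households=float(wt),
                unadjusted_rate=nu / wt if wt else np.nan,
                adjusted_rate=na / wt if wt else np.nan,
                n_poor_unadjusted=nu,
                n_poor_adjusted=na,
            ).__dict__
        )
    return pd.DataFrame(rows)


def one_in_k(rate: float) -> str:
    """Render a headcount rate as the field's '1 in k' phrasing."""
    if rate is None or np.isnan(rate) or rate <= 0:
        return "1 in ∞"
    return f"1 in {round(1.0 / rate)}"


def headcount_ratio_report(results: pd.DataFrame) -> pd.DataFrame:
    """Comparison table: rates, '1 in k' phrasing, ratio to the no-disability group."""
    out = results.copy()
    base_rows = out[out["group"] == "no_disability"]
    base = float(base_rows["unadjusted_rate"].iloc[0]) if len(base_rows) else np.nan
    out["one_in_k_unadjusted"] = out["unadjusted_rate"].map(one_in_k)
    out["one_in_k_adjusted"] = out["adjusted_rate"].map(one_in_k)
    out["rate_ratio_vs_no_disability"] = (out["adjusted_rate"] / base).round(1)
    return out


class PovertyAdjuster(BaseEstimator):
    """Applies a multiplier table to household poverty lines and counts the poor.

    fit() stores the multiplier table; transform() appends ``multiplier``
    and ``adjusted_line`` columns; :meth:`headcount` produces the group
    rates and the "1 in k" report.
    """

    def __init__(
        self,
        policy: MultiplierPolicy = MultiplierPolicy(),
        threshold: str = "higher",
        weight_col: str | None = None,
    ):
        self.policy = policy
        self.threshold = threshold
        self.weight_col = weight_col

    def fit(self, table: MultiplierTable, y=None):
        self.table_ = table
        return self

    def transform(self, households: pd.DataFrame) -> pd.DataFrame:
        thr = self.threshold
        out = households.copy()
        n = len(out)
        flags = np.column_stack([out[f"hh_{d}_{thr}"].to_numpy(bool) for d in DOMAINS])
        if self.policy.source == "bottom40_pooled":
            qlab = np.full(n, BOTTOM40, dtype=object)
        else:
            if "quintile" not in out.columns:
                raise ValueError("per_quintile policy needs a quintile column")
            qlab = np.array([MultiplierTable.quintile_label(q) for q in out["quintile"]], dtype=object)
        # per-domain contribution matrix; -inf = no contribution
        contrib = np.full((n, len(DOMAINS)), -np.inf)
        excluded = np.zeros((n, len(DOMAINS)), dtype=bool)
        for j, d in enumerate(DOMAINS):
            col = flags[:, j]
            for ql in np.unique(qlab[col]):
                q = BOTTOM40 if ql == BOTTOM40 else int(ql[1:])
                sel = col & (qlab == ql)
                present = (
                    (self.table_.df["type"] == d)
                    & (self.table_.df["quintile"] == ql)
                    & (self.table_.df["threshold"] == thr)
                ).any()
                if not present:
                    raise KeyError(f"multiplier table has no {d}/{ql}/{thr} row")
                cell = self.table_.cell(d, q, thr)
                if cell is None:
                    if self.policy.blank_rule == "treat_as_zero":
                        contrib[sel, j] = 0.0
                    else:
                        excluded[sel, j] = True
                else:
                    contrib[sel, j] = cell / 100.0
        any_flag = flags.any(axis=1)
        valid = flags & ~excluded
        ms = np.where(any_flag, contrib.max(axis=1), 0.0)
        ms[any_flag & ~valid.any(axis=1)] = np.nan  # every flagged cell blank-excluded
        out["multiplier"] = ms
        valid = ~np.isnan(ms)
        out["adjusted_line"] = np.nan
        out.loc[valid, "adjusted_line"] = adjusted_line(
            out.loc[valid, "poverty_line"].to_numpy(float), ms[valid]
        )
        return out

    def headcount(self, households: pd.DataFrame, use_adjusted: bool = True) -> pd.DataFrame:
        df = households if "multiplier" in households.columns else self.transform(households)
        res = poverty_headcount(df, use_adjusted=use_adjusted, weight_col=self.weight_col)
        return headcount_ratio_report(res)
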