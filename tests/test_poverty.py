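"""Poverty-line adjustment and headcount ratios."""

import numpy as np
import pandas as pd
import pytest

from discost import (
    MultiplierPolicy,
    MultiplierTable,
    PovertyAdjuster,
    adjusted_line,
    example_multiplier_table,
    household_multiplier,
    poverty_headcount,
    headcount_ratio_report,
)
from discost.domains import DOMAINS
from discost.poverty import one_in_k


@pytest.fixture(scope="module")
def table():
    return example_multiplier_table()


class TestHouseholdMultiplier:
    def test_multiple_types_take_the_highest(self, table):
        # published Q1 moderate/severe cells: sight 4.9%, hearing 8.3%
        m = household_multiplier({"seeing": True, "hearing": True}, table, threshold="higher")
        assert m == pytest.approx(0.083)

    def test_no_flags_zero(self, table):
        assert household_multiplier({}, table) == 0.0

    def test_blank_cell_policies(self, table):
        # self-care B40 higher is blank in the example table (Q1-Q4 all blank)
        flags = {"selfcare": True}
        assert household_multiplier(flags, table, threshold="higher") == 0.0
        excl = MultiplierPolicy(blank_rule="exclude_household")
        assert household_multiplier(flags, table, excl, threshold="higher") is None

    def test_missing_type_row_is_configuration_error(self):
        small = MultiplierTable.from_cells({("seeing", "B40"): 5.0}, threshold="higher")
        with pytest.raises(KeyError):
            household_multiplier({"hearing": True}, small, threshold="higher")

    def test_per_quintile_source_needs_quintile(self, table):
        pol = MultiplierPolicy(source="per_quintile")
        with pytest.raises(ValueError):
            household_multiplier({"seeing": True}, table, pol, threshold="higher")
        m = household_multiplier({"seeing": True}, table, pol, threshold="higher", quintile=5)
        assert m == pytest.approx(0.224)


def test_adjusted_line():
    assert adjusted_line(500_000, 0.20) == 600_000
    assert adjusted_line(500_000, 0.0) == 500_000
    assert adjusted_line(1.0, 0.224) == pytest.approx(1.224)
    with pytest.raises(ValueError):
        adjusted_line(-1.0, 0.2)
    with pytest.raises(ValueError):
        adjusted_line(1.0, -0.2)


def _random_households(n=400, seed=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "exp_pc": rng.lognormal(13, 0.6, n),
            "poverty_line": rng.choice([400_000, 450_000, 500_000], n),
            "multiplier": rng.choice([0.0, 0.05, 0.083, 0.224], n),
        }
    )
    higher = rng.random(n) < 0.2
    lower = higher | (rng.random(n) < 0.2)
    df["hh_disabled_lower"] = lower
    df["hh_disabled_higher"] = higher
    df.loc[~lower, "multiplier"] = 0.0
    return df


class TestHeadcount:
    def test_matches_bruteforce_recount(self):
        df = _random_households()
        res = poverty_headcount(df).set_index("group")
        for name, sel in {
            "no_disability": ~df.hh_disabled_lower,
            "disability_lower": df.hh_disabled_lower,
            "disability_higher": df.hh_disabled_higher,
        }.items():
            sub = df[sel]
            poor_un = sum(1 for r in sub.itertuples() if r.exp_pc < r.poverty_line)
            poor_adj = sum(
                1
                for r in sub.itertuples()
                if r.exp_pc < r.poverty_line * (1 + r.multiplier)
            )
            assert res.loc[name, "n_poor_unadjusted"] == poor_un
            assert res.loc[name, "n_poor_adjusted"] == poor_adj
            assert res.loc[name, "adjusted_rate"] == pytest.approx(poor_adj / len(sub))

    def test_zero_multipliers_reproduce_unadjusted_rates(self):
        df = _random_households()
        df["multiplier"] = 0.0
        res = poverty_headcount(df)
        assert (res["adjusted_rate"] == res["unadjusted_rate"]).all()

    def test_rates_monotone_in_multipliers(self):
        df = _random_households()
        lo = poverty_headcount(df)
        df2 = df.copy()
        df2["multiplier"] = df2["multiplier"] + 0.10
        hi = poverty_headcount(df2)
        assert (hi["adjusted_rate"] >= lo["adjusted_rate"] - 1e-12).all()
        assert (lo["adjusted_rate"] >= lo["unadjusted_rate"] - 1e-12).all()

    def test_all_above_lines_gives_zero_rates(self):
        df = _random_households()
        df["exp_pc"] = 10 * df["poverty_line"]
        res = poverty_headcount(df)
        assert (res["adjusted_rate"] == 0).all()

    def test_higher_group_nested_in_lower(self):
        df = _random_households()
        res = poverty_headcount(df).set_index("group")
        assert res.loc["disability_higher", "n_households"] <= res.loc[
            "disability_lower", "n_households"
        ]

    def test_missing_line_rejected(self):
        df = _random_households().drop(columns="poverty_line")
        with pytest.raises(ValueError):
            poverty_headcount(df)


def test_one_in_k_phrasing():
    assert one_in_k(0.25) == "1 in 4"
    assert one_in_k(0.083) == "1 in 12"
    assert one_in_k(0.0) == "1 in ∞"
    rep = headcount_ratio_report(
        pd.DataFrame(
            [
                {"group": "no_disability", "unadjusted_rate": 0.083, "adjusted_rate": 0.083},
                {"group": "disability_higher", "unadjusted_rate": 0.15, "adjusted_rate": 0.25},
            ]
        )
    )
    row = rep.set_index("group").loc["disability_higher"]
    assert row["one_in_k_adjusted"] == "1 in 4"
    assert row["rate_ratio_vs_no_disability"] == pytest.approx(3.0)


def test_adjuster_transform_matches_scalar_rule(table):
    rng = np.random.default_rng(5)
    n = 60
    hh = pd.DataFrame(
        {
            "exp_pc": rng.lognormal(13, 0.5, n),
            "poverty_line": np.full(n, 450_000.0),
        }
    )
    for d in DOMAINS:
        hh[f"hh_{d}_higher"] = rng.random(n) < 0.25
    hh["hh_disabled_higher"] = hh[[f"hh_{d}_higher" for d in DOMAINS]].any(axis=1)
    hh["hh_disabled_lower"] = hh["hh_disabled_higher"]
    adj = PovertyAdjuster().fit(table)
    out = adj.transform(hh)
    for i, row in out.iterrows():
        flags = {d: bool(row[f"hh_{d}_higher"]) for d in DOMAINS}
        expect = household_multiplier(flags, table, threshold="higher")
        assert row["multiplier"] == pytest.approx(expect)
        if expect > 0:
            assert row["adjusted_line"] == pytest.approx(450_000 * (1 + expect))
    rates = adj.headcount(out)
    assert {"one_in_k_adjusted", "rate_ratio_vs_no_disability"} <= set(rates.columns)
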