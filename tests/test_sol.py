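"""SOL regressions, quintiles, the E = -beta/alpha multiplier machinery."""

import numpy as np
import pandas as pd
import pytest

from discost import (
    MultiplierTable,
    SolFit,
    StratumUnestimableError,
    assign_quintiles,
    build_multiplier_table,
    extra_cost_from_fit,
    fit_stratum,
    normalize_expenditure,
    to_percent,
)
from discost.domains import DOMAINS


class TestNormalizeExpenditure:
    def test_ratio_and_log(self):
        assert normalize_expenditure(1_000_000, 500_000) == 2.0
        assert normalize_expenditure(500_000, 500_000) == 1.0
        assert normalize_expenditure(1_000_000, 500_000, mode="log") == pytest.approx(np.log(2))

    def test_regional_cost_of_living_cancels(self):
        # same exp/line ratio in two regions -> identical welfare ratio
        assert normalize_expenditure(800_000, 400_000) == normalize_expenditure(
            1_200_000, 600_000
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_expenditure(0, 500_000)
        with pytest.raises(ValueError):
            normalize_expenditure(500_000, -1)


class TestAssignQuintiles:
    def test_even_split(self):
        q = assign_quintiles(np.arange(1, 11, dtype=float))
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_dominant_weight_defines_cuts(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        q = assign_quintiles(y, w)
        # all mass at y=3: anything <= 3 is Q1..Q5 by ECDF position
        assert q[2] == 5  # carries the full distribution
        assert (q[:2] == 1).all() and (q[3:] == 5).all()

    def test_matches_weighted_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.lognormal(0, 1, 400)
        w = rng.uniform(0.2, 3.0, 400)
        q = assign_quintiles(y, w)
        total = w.sum()
        for i in range(len(y)):
            f = w[y <= y[i]].sum() / total  # brute-force weighted ECDF
            expect = min(5, max(1, int(np.ceil(f * 5 - 1e-12))))
            assert q[i] == expect

    def test_degenerate_values_warn(self):
        with pytest.warns(UserWarning):
            assign_quintiles(np.array([1.0, 1.0, 1.0, 1.0, 2.0]))


class TestFitStratum:
    def test_noiseless_identification_is_exact(self, noiseless_survey, noiseless_households):
        """With zero noise and a linear index, beta/alpha = -C to machine precision."""
        hh = noiseless_households
        cfg = noiseless_survey.config
        mean_y_q = hh.groupby("quintile")["y"].mean()
        for d, q in [("seeing", 2), ("walking", 4), ("selfcare", 5)]:
            fit = fit_stratum(hh, d, q, "higher", controls=())
            c_true = cfg.true_cost_fraction[(d, q)] * mean_y_q[q]
            assert -fit.beta_hat / fit.alpha_hat == pytest.approx(c_true, abs=1e-9)
            assert fit.alpha_hat == pytest.approx(cfg.alpha_true, abs=1e-9)

    def test_no_disabled_households_unestimable(self, midsize_households):
        hh = midsize_households.copy()
        hh["hh_seeing_higher"] = False
        with pytest.raises(StratumUnestimableError):
            fit_stratum(hh, "seeing", 1, "higher")

    def test_collinear_control_dropped_with_warning(self, midsize_households):
        hh = midsize_households.copy()
        hh["dup"] = 2.0 * hh["hh_size"]
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_stratum(hh, "seeing", 3, "higher", controls=("hh_size", "dup"))
        assert "dup" not in fit.gamma_hat.index

    def test_noisy_recovery_within_tolerance(self):
        """True fraction 0.20 recovered within +/-0.02 from a 50,000-household
        noisy stratum with the full expenditure spread."""
        rng = np.random.default_rng(6)
        n = 50_000
        y = 2.0 * rng.lognormal(0.0, 0.5, n)
        d = rng.random(n) < 0.2
        c = 0.20 * y.mean()
        hh = pd.DataFrame(
            {
                "y": y,
                "quintile": 1,  # a single stratum
                "sol_index": 10 + 6 * (y - c * d) + rng.normal(0, 8, n),
                "hh_seeing_higher": d,
                "hh_n_domains_higher": d.astype(int),
            }
        )
        fit = fit_stratum(hh, "seeing", 1, "higher", controls=())
        frac_hat = (-fit.beta_hat / fit.alpha_hat) / y.mean()
        assert frac_hat == pytest.approx(0.20, abs=0.02)


def _fit(alpha, beta, va=0.01, vb=0.01, cab=0.0, p=0.01, mean_y=2.5):
    return SolFit(
        domain="seeing",
        quintile=1,
        threshold="higher",
        alpha_hat=alpha,
        beta_hat=beta,
        gamma_hat=pd.Series(dtype=float),
        intercept=0.0,
        cov_alpha_beta=np.array([[va, cab], [cab, vb]]),
        n_obs=100,
        n_disabled=10,
        p_beta=p,
        mean_y=mean_y,
    )


class TestExtraCost:
    def test_ratio_formula(self):
        est = extra_cost_from_fit(_fit(2.0, -0.4))
        assert est.e_hat == pytest.approx(0.2)
        assert est.valid and est.significant

    def test_null_beta(self):
        est = extra_cost_from_fit(_fit(2.0, 0.0, p=0.9))
        assert est.e_hat == 0.0 and not est.significant

    def test_negative_alpha_flagged_invalid(self):
        assert not extra_cost_from_fit(_fit(-1.0, -0.4)).valid

    def test_delta_method_closed_form(self):
        a, b, va, vb, cab = 2.0, -0.5, 0.04, 0.09, 0.01
        est = extra_cost_from_fit(_fit(a, b, va, vb, cab))
        expect = np.sqrt(vb / a**2 + b**2 * va / a**4 - 2 * b * cab / a**3)
        assert est.se_e == pytest.approx(expect)


class TestToPercent:
    def test_levels(self):
        assert to_percent(0.5, 2.5) == pytest.approx(20.0)
        assert to_percent(0.0, 2.5) == 0.0

    def test_log_mode(self):
        assert to_percent(0.1823, 1.0, mode="log") == pytest.approx(20.0, abs=0.01)


def test_index_scale_invariance(midsize_households):
    """Scaling the asset index by c scales alpha and beta but leaves E unchanged."""
    hh = midsize_households
    f1 = fit_stratum(hh, "hearing", 4, "higher")
    hh2 = hh.copy()
    hh2["sol_index"] = 3.7 * hh2["sol_index"]
    f2 = fit_stratum(hh2, "hearing", 4, "higher")
    assert f2.alpha_hat == pytest.approx(3.7 * f1.alpha_hat)
    assert f2.beta_hat == pytest.approx(3.7 * f1.beta_hat)
    assert -f2.beta_hat / f2.alpha_hat == pytest.approx(-f1.beta_hat / f1.alpha_hat)
    assert f2.p_beta == pytest.approx(f1.p_beta, abs=1e-10)


class TestMultiplierTable:
    def test_blanking_rule_follows_p_value(self, midsize_households):
        table, fits = build_multiplier_table(
            midsize_households, thresholds=("higher",), include_bottom40=True
        )
        for row in table.df.itertuples():
            key = (row.type, row.quintile, row.threshold)
            if key not in fits:
                assert row.blank  # unestimable
                continue
            est = extra_cost_from_fit(fits[key])
            assert row.blank == (not (est.significant and est.valid))
            if not row.blank:
                assert row.percent == pytest.approx(est.percent)

    def test_bottom40_rows_present(self, midsize_households):
        table, _ = build_multiplier_table(
            midsize_households, thresholds=("higher",), include_bottom40=True
        )
        assert set(table.df[table.df.quintile == "B40"].type) == set(DOMAINS)

    def test_cell_lookup_and_csv_round_trip(self, tmp_path, midsize_households):
        table, _ = build_multiplier_table(midsize_households, thresholds=("higher",))
        p = tmp_path / "table.csv"
        table.to_csv(p)
        back = MultiplierTable.read_csv(p)
        pd.testing.assert_frame_equal(
            back.df, table.df, check_dtype=False, check_exact=False
        )
        blank_row = table.df[table.df.blank].iloc[0]
        assert table.cell(blank_row.type, blank_row.quintile, "higher") is None
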