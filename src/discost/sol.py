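"""Standard-of-living (SOL) regressions and the extra-cost multiplier table.

The SOL (expenditure-equivalence) approach regresses a material
standard-of-living index S on normalized household expenditure Y, a
disability indicator D and demographic controls X:

    S = alpha * Y + beta * D + gamma' X + k

Households that divert part of their spending to disability-related needs
accumulate fewer assets at equal expenditure, so beta < 0, and the extra
cost of disability is the cross-elasticity

    E = -beta / alpha

the additional (poverty-line-normalized) expenditure a disability household
needs to reach the standard of living of a comparable household without
disability. Regressions are run separately by disability type, expenditure
quintile and severity threshold; cells whose disability coefficient is not
significant at the 10% level are blanked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .domains import DOMAINS, QUINTILES, check_threshold

#: Default demographic controls (household-level).
DEFAULT_CONTROLS: tuple[str, ...] = ("hh_size", "urban", "head_age", "head_sex", "head_edu")

#: Label for the pooled bottom-40% (Q1 + Q2) stratum.
BOTTOM40 = "B40"


class StratumUnestimableError(ValueError):
    """Raised when a stratum has no identifying variation (maps to a BLANK cell)."""


# ---------------------------------------------------------------------------
# expenditure normalization and quintiles


def normalize_expenditure(exp_pc, poverty_line, mode: str = "levels"):
    """Normalized welfare ratio Y = per-capita expenditure / regional poverty line.

    Dividing by the regional line removes cost-of-living variation across
    regions: households with equal exp/line ratios are treated as equally
    well off. ``mode="log"`` returns log(Y).
    """
    exp_pc = np.asarray(exp_pc, dtype=float)
    poverty_line = np.asarray(poverty_line, dtype=float)
    if (exp_pc <= 0).any() or (poverty_line <= 0).any():
        raise ValueError("expenditure and poverty lines must be positive")
    y = exp_pc / poverty_line
    if mode == "log":
        return np.log(y)
    if mode != "levels":
        raise ValueError(f"unknown expenditure mode {mode!r}")
    return y


def assign_quintiles(y, weights=None) -> np.ndarray:
    """Weighted expenditure quintiles Q1 (poorest) .. Q5 (richest) as ints 1..5.

    Uses the weighted ECDF F(v) = sum of weights with y <= v over total
    weight; an observation lands in quintile ceil(5*F), with ties exactly at
    a cut point assigned to the lower quintile. Deterministic under a stable
    sort.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 observations to form quintiles")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    if len(np.unique(y)) < 5:
        warnings.warn("fewer than 5 distinct values; quintiles are degenerate")
    order = np.argsort(y, kind="stable")
    cw = np.cumsum(w[order])
    frac = cw / cw[-1]
    # ties share the largest ECDF value of their y
    ys = y[order]
    for start in np.flatnonzero(np.r_[True, np.diff(ys) != 0]):
        stop = start
        while stop + 1 < len(ys) and ys[stop + 1] == ys[start]:
            stop += 1
        frac[start : stop + 1] = frac[stop]
    q_sorted = np.minimum(5, np.ceil(frac * 5 - 1e-12).astype(int))
    q_sorted = np.maximum(q_sorted, 1)
    out = np.empty(len(y), dtype=int)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# stratum regressions


@dataclass
class SolFit:
    """OLS output for one (type, quintile, threshold) stratum."""

    domain: str
    quintile: object  # 1..5 or BOTTOM40
    threshold: str
    alpha_hat: float
    beta_hat: float
    gamma_hat: pd.Series
    intercept: float
    cov_alpha_beta: np.ndarray  # 2x2 covariance of (alpha_hat, beta_hat)
    n_obs: int
    n_disabled: int
    p_beta: float
    mean_y: float  # mean normalized expenditure of the percent base population

    @property
    def se_beta(self) -> float:
        return float(np.sqrt(self.cov_alpha_beta[1, 1]))


@dataclass
class ExtraCostEstimate:
    """E = -beta/alpha with a delta-method standard error."""

    e_hat: float
    se_e: float
    percent: float
    p_beta: float
    significant: bool
    valid: bool  # alpha_hat > 0 (index must rise with expenditure)


def _stratum_mask(df: pd.DataFrame, domain: str, quintile, threshold: str, exclusive: bool):
    flag = df[f"hh_{domain}_{threshold}"].to_numpy(bool)
    ndom = df[f"hh_n_domains_{threshold}"].to_numpy()
    if quintile == BOTTOM40:
        in_q = df["quintile"].isin([1, 2]).to_numpy()
    else:
        in_q = (df["quintile"] == quintile).to_numpy()
    if exclusive:
        keep = in_q & ((ndom == 0) | (flag & (ndom == 1)))
    else:
        keep = in_q
    return keep, flag


def fit_stratum(
    households: pd.DataFrame,
    domain: str,
    quintile,
    threshold: str,
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    exclusive: bool = True,
    weight_col: str | None = None,
    mean_y_base: float | None = None,
    index_col: str = "sol_index",
) -> SolFit:
    """OLS of the asset index on (Y, D, controls) within one stratum.

    ``households`` needs columns ``y`` (normalized expenditure),
    ``quintile``, the index column, and the ``hh_*_<threshold>`` flags from
    the classifier. D marks households with a member flagged in ``domain``;
    with ``exclusive=True`` (the default, matching the single-type design)
    households flagged in any *other* domain are dropped, so the comparison
    is single-type-``domain`` households versus households with no
    disability at the threshold.

    Raises :class:`StratumUnestimableError` when D has no variation or the
    stratum is too small; such strata become BLANK cells downstream.
    """
    check_threshold(threshold)
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    keep, flag = _stratum_mask(households, domain, quintile, threshold, exclusive)
    sub = households.loc[keep]
    d = flag[keep].astype(float)
    n_dis = int(d.sum())
    if n_dis == 0 or n_dis == len(d):
        raise StratumUnestimableError(
            f"no variation in disability status for {domain}/{quintile}/{threshold}"
        )
    use_controls = [c for c in controls if c in sub.columns]
    missing = set(controls) - set(use_controls)
    if missing:
        warnings.warn(f"controls absent from household table, skipped: {sorted(missing)}")
    X = pd.DataFrame({"y": sub["y"].to_numpy(float), "D": d}, index=sub.index)
    kept_controls = []
    for c in use_controls:
        col = sub[c].to_numpy(float)
        trial = np.column_stack([np.ones(len(X)), X.to_numpy()] + [sub[k].to_numpy(float) for k in kept_controls] + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept_controls.append(c)
        else:
            warnings.warn(f"dropping collinear control {c!r} in {domain}/{quintile}/{threshold}")
    for c in kept_controls:
        X[c] = sub[c].to_numpy(float)
    if len(X) < X.shape[1] + 2:
        raise StratumUnestimableError(
            f"stratum {domain}/{quintile}/{threshold} too small (n={len(X)})"
        )
    exog = sm.add_constant(X, has_constant="add")
    endog = sub[index_col].to_numpy(float)
    if weight_col is not None:
        res = sm.WLS(endog, exog, weights=sub[weight_col].to_numpy(float)).fit()
    else:
        res = sm.OLS(endog, exog).fit()
    cov = res.cov_params()
    cov_ab = cov.loc[["y", "D"], ["y", "D"]].to_numpy()
    if mean_y_base is None:
        mean_y_base = float(sub["y"].mean())
    return SolFit(
        domain=domain,
        quintile=quintile,
        threshold=threshold,
        alpha_hat=float(res.params["y"]),
        beta_hat=float(res.params["D"]),
        gamma_hat=res.params[kept_controls],
        intercept=float(res.params["const"]),
        cov_alpha_beta=cov_ab,
        n_obs=int(res.nobs),
        n_disabled=n_dis,
        p_beta=float(res.pvalues["D"]),
        mean_y=float(mean_y_base),
    )


def extra_cost_from_fit(fit: SolFit, alpha_level: float = 0.10, mode: str = "levels") -> ExtraCostEstimate:
    """Extra-cost estimate E = -beta/alpha with its delta-method SE.

    The SE follows from a first-order expansion of the ratio:
        Var(E) = Var(b)/a^2 + b^2 Var(a)/a^4 - 2 b Cov(a,b)/a^3.
    ``significant`` applies the two-sided 10% rule on beta used for
    blanking; ``valid`` is False when alpha_hat <= 0 (an index that does
    not rise with expenditure cannot identify a cost).
    """
    a, b = fit.alpha_hat, fit.beta_hat
    va = fit.cov_alpha_beta[0, 0]
    vb = fit.cov_alpha_beta[1, 1]
    cab = fit.cov_alpha_beta[0, 1]
    if a == 0:
        e, se = np.nan, np.nan
    else:
        e = -b / a
        var_e = vb / a**2 + b**2 * va / a**4 - 2 * b * cab / a**3
        se = float(np.sqrt(max(var_e, 0.0)))
    return ExtraCostEstimate(
        e_hat=float(e),
        se_e=se,
        percent=to_percent(e, fit.mean_y, mode=mode),
        p_beta=fit.p_beta,
        significant=bool(fit.p_beta <= alpha_level),
        valid=bool(a > 0),
    )


def to_percent(e: float, stratum_mean_y: float, mode: str = "levels") -> float:
    """Express E as a percentage multiplier.

    In levels mode E is in poverty-line units and the multiplier is taken
    relative to the stratum's mean normalized expenditure:
    100 * E / mean(Y). In log mode E is in log points and the multiplier is
    100 * (exp(E) - 1), independent of the base.
    """
    if mode == "log":
        return float(100.0 * (np.exp(e) - 1.0))
    if stratum_mean_y <= 0:
        raise ValueError("stratum mean Y must be positive")
    return float(100.0 * e / stratum_mean_y)


# ---------------------------------------------------------------------------
# the multiplier table


@dataclass
class MultiplierTable:
    """Extra-cost percentages by (type, quintile, threshold), BLANK-aware.

    Backed by a tidy DataFrame with columns ``type``, ``quintile``
    ("Q1".."Q5" or "B40"), ``threshold``, ``percent`` (NaN when blank),
    ``e_hat``, ``p_value``, ``n_obs``, ``n_disabled``, ``blank``.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    @staticmethod
    def quintile_label(q) -> str:
        return q if isinstance(q, str) else f"Q{int(q)}"

    def cell(self, dtype: str, quintile, threshold: str) -> float | None:
        """Percent multiplier for a cell, or None when the cell is blank/absent."""
        ql = self.quintile_label(quintile)
        m = self.df[
            (self.df["type"] == dtype)
            & (self.df["quintile"] == ql)
            & (self.df["threshold"] == threshold)
        ]
        if m.empty or bool(m["blank"].iloc[0]):
            return None
        return float(m["percent"].iloc[0])

    def populated(self) -> pd.DataFrame:
        return self.df[~self.df["blank"]].copy()

    @property
    def n_blank(self) -> int:
        return int(self.df["blank"].sum())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MultiplierTable":
        df = pd.read_csv(path)
        df["blank"] = df["blank"].astype(bool)
        return cls(df)

    @classmethod
    def from_cells(cls, cells: dict, threshold: str = "higher") -> "MultiplierTable":
        """Build from {(type, quintile): percent-or-None}; None means BLANK."""
        rows = []
        for (dtype, q), pct in cells.items():
            rows.append(
                {
                    "type": dtype,
                    "quintile": cls.quintile_label(q),
                    "threshold": threshold,
                    "percent": np.nan if pct is None else float(pct),
                    "e_hat": np.nan,
                    "p_value": np.nan,
                    "n_obs": np.nan,
                    "n_disabled": np.nan,
                    "blank": pct is None,
                }
            )
        return cls(pd.DataFrame(rows))


def build_multiplier_table(
    households: pd.DataFrame,
    thresholds: tuple[str, ...] = ("lower", "higher"),
    domains: tuple[str, ...] = DOMAINS,
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    alpha_level: float = 0.10,
    exclusive: bool = True,
    include_bottom40: bool = False,
    weight_col: str | None = None,
    mode: str = "levels",
) -> tuple[MultiplierTable, dict]:
    """Run every stratum regression and assemble the multiplier table.

    ``households`` must carry ``y``, ``quintile``, ``sol_index`` and the
    classifier's household flags. Cells are BLANK when the stratum is
    unestimable, alpha_hat <= 0, or the disability coefficient misses
    two-sided significance at ``alpha_level`` (10% by default). The percent
    base for each quintile cell is the mean Y over *all* households in the
    quintile (the "typical" household of that stratum); bottom-40 rows use
    the mean over Q1+Q2.

    Returns the table and a dict of the underlying :class:`SolFit` objects
    keyed by (type, quintile-label, threshold).
    """
    w = None if weight_col is None else households[weight_col].to_numpy(float)
    base_means = {}
    for q in QUINTILES:
        sel = households["quintile"] == q
        yq = households.loc[sel, "y"]
        wq = None if w is None else w[sel.to_numpy()]
        base_means[q] = float(np.average(yq, weights=wq)) if len(yq) else np.nan
    sel40 = households["quintile"].isin([1, 2])
    base_means[BOTTOM40] = float(
        np.average(households.loc[sel40, "y"], weights=None if w is None else w[sel40.to_numpy()])
    )
    quintile_list = list(QUINTILES) + ([BOTTOM40] if include_bottom40 else [])
    rows, fits = [], {}
    for threshold in thresholds:
        for domain in domains:
            for q in quintile_list:
                ql = MultiplierTable.quintile_label(q)
                row = {
                    "type": domain,
                    "quintile": ql,
                    "threshold": threshold,
                    "percent": np.nan,
                    "e_hat": np.nan,
                    "p_value": np.nan,
                    "n_obs": 0,
                    "n_disabled": 0,
                    "blank": True,
                }
                try:
                    fit = fit_stratum(
                        households,
                        domain,
                        q,
                        threshold,
                        controls=controls,
                        exclusive=exclusive,
                        weight_col=weight_col,
                        mean_y_base=base_means[q],
                    )
                except StratumUnestimableError:
                    rows.append(row)
                    continue
                fits[(domain, ql, threshold)] = fit
                est = extra_cost_from_fit(fit, alpha_level=alpha_level, mode=mode)
                row.update(
                    p_value=fit.p_beta,
                    n_obs=fit.n_obs,
                    n_disabled=fit.n_disabled,
                    e_hat=est.e_hat,
                )
                if est.valid and est.significant:
                    row.update(percent=est.percent, blank=False)
                rows.append(row)
    return MultiplierTable(pd.DataFrame(rows)), fits


# ---------------------------------------------------------------------------
# nonparametric oracle


def compensating_expenditure_gap(
    households: pd.DataFrame,
    domain: str,
    threshold: str = "higher",
    quintile=None,
    exclusive: bool = True,
    n_grid: int = 11,
    index_col: str = "sol_index",
) -> float:
    """Compensating-expenditure estimate of the extra cost, regression-free.

    Interpolates the index-versus-Y profiles of the disability and
    no-disability groups and solves, at several Y grid points, for the
    extra normalized expenditure delta that lifts a disability household to
    the no-disability standard of living: S_dis(Y + delta) = S_nodis(Y).
    Returns the median delta over the grid. With noiseless linear data this
    equals -beta/alpha exactly; it serves as an independent check on the
    regression route.
    """
    if quintile is not None:
        keep, flag = _stratum_mask(households, domain, quintile, threshold, exclusive)
    else:
        flag = households[f"hh_{domain}_{threshold}"].to_numpy(bool)
        ndom = households[f"hh_n_domains_{threshold}"].to_numpy()
        keep = ((ndom == 0) | (flag & (ndom == 1))) if exclusive else np.ones(len(households), bool)
    sub = households.loc[keep]
    d = flag[keep]
    y_d, s_d = sub.loc[d, "y"].to_numpy(float), sub.loc[d, index_col].to_numpy(float)
    y_n, s_n = sub.loc[~d, "y"].to_numpy(float), sub.loc[~d, index_col].to_numpy(float)
    if len(y_d) < 2 or len(y_n) < 2:
        raise StratumUnestimableError("need at least two households in each group")
    od, on = np.argsort(y_d), np.argsort(y_n)
    y_d, s_d = y_d[od], s_d[od]
    y_n, s_n = y_n[on], s_n[on]
    # anchor the grid on the disability group's own expenditures and invert
    # the comparison group's profile: S_dis(y1) = S_nodis(y1 - delta)
    deltas = []
    for y1 in np.quantile(y_d, np.linspace(0.1, 0.9, n_grid)):
        target = np.interp(y1, y_d, s_d)
        g = lambda y0: np.interp(y0, y_n, s_n) - target
        if g(y_n.min()) * g(y_n.max()) > 0:  # target outside comparison range
            continue
        y0 = brentq(g, y_n.min(), y_n.max(), xtol=1e-12)
        deltas.append(y1 - y0)
    if not deltas:
        raise StratumUnestimableError("no grid point admitted a compensating gap")
    return float(np.median(deltas))


# ---------------------------------------------------------------------------
# estimator facade


class SolExtraCostEstimator(BaseEstimator):
    """Standard-of-living extra-cost estimator over a classified household table.

    Fit on a household DataFrame carrying per-capita expenditure
    (``exp_pc``), the regional poverty line (``poverty_line``), either a
    ``sol_index`` column or binary ``asset_*``/``dwell_*`` indicators, and
    the household disability flags produced by
    :meth:`discost.wg.WashingtonGroupClassifier.household_flags`.

    Fitted attributes
    -----------------
    multiplier_table_ : :class:`MultiplierTable`
    fits_ : dict mapping (type, quintile, threshold) to :class:`SolFit`
    households_ : the augmented household table (y, quintile, sol_index)

    Parameters mirror the analysis choices: severity thresholds, the
    demographic control list, the 10% blanking level, levels-vs-log
    expenditure, exclusive single-type strata, pooled bottom-40% rows and
    optional survey weights.
    """

    def __init__(
        self,
        thresholds=("lower", "higher"),
        domains=DOMAINS,
        controls=DEFAULT_CONTROLS,
        alpha_level=0.10,
        expenditure_mode="levels",
        exclusive_strata=True,
        include_bottom40=True,
        weight_col=None,
    ):
        self.thresholds = thresholds
        self.domains = domains
        self.controls = controls
        self.alpha_level = alpha_level
        self.expenditure_mode = expenditure_mode
        self.exclusive_strata = exclusive_strata
        self.include_bottom40 = include_bottom40
        self.weight_col = weight_col

    def fit(self, X: pd.DataFrame, y=None):
        from .assets import index_from_frame

        df = X.copy()
        df["y"] = normalize_expenditure(
            df["exp_pc"], df["poverty_line"], mode=self.expenditure_mode
        )
        w = None if self.weight_col is None else df[self.weight_col].to_numpy(float)
        df["quintile"] = assign_quintiles(df["y"].to_numpy(float), w)
        if "sol_index" not in df.columns:
            df["sol_index"] = index_from_frame(df)
        self.multiplier_table_, self.fits_ = build_multiplier_table(
            df,
            thresholds=tuple(self.thresholds),
            domains=tuple(self.domains),
            controls=tuple(self.controls),
            alpha_level=self.alpha_level,
            exclusive=self.exclusive_strata,
            include_bottom40=self.include_bottom40,
            weight_col=self.weight_col,
            mode=self.expenditure_mode,
        )
        self.households_ = df
        self.n_strata_ = len(self.multiplier_table_.df)
        return self
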