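"""Disability classification from Washington Group Short Set responses.

A member is flagged in a domain when their response reaches the threshold
severity: ``lower`` = some difficulty or worse (slight/moderate/severe),
``higher`` = a lot of difficulty or worse (moderate/severe). A member is
disabled when at least one domain is flagged; one flagged domain is a
*single* disability, two or more a *multiple* disability. Household flags
are the member-wise union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .domains import DOMAINS, WG_COLUMNS, check_threshold


@dataclass(frozen=True)
class DisabilityProfile:
    """Classification of one member at one severity threshold."""

    threshold: str
    domain_flags: tuple[bool, ...]

    def __post_init__(self):
        if len(self.domain_flags) != len(DOMAINS):
            raise ValueError("domain_flags must have one entry per WG domain")

    @property
    def n_domains(self) -> int:
        return int(sum(self.domain_flags))

    @property
    def disabled(self) -> bool:
        return self.n_domains >= 1

    @property
    def multiplicity(self) -> str:
        n = self.n_domains
        return "none" if n == 0 else ("single" if n == 1 else "multiple")


def _validate_codes(values: np.ndarray) -> None:
    bad = ~np.isin(values, (0, 1, 2, 3))
    if bad.any():
        raise ValueError(
            f"WG response codes must be in {{0,1,2,3}}; found {np.unique(values[bad])}"
        )


def classify_member(responses, threshold: str) -> DisabilityProfile:
    """Classify one member's six WG-SS responses at a severity threshold.

    Parameters
    ----------
    responses : sequence of six ints in {0,1,2,3} or mapping domain -> code
        Responses in the canonical domain order (seeing, hearing, walking,
        remembering, communicating, self-care).
    threshold : {"lower", "higher"}
    """
    cut = check_threshold(threshold)
    if isinstance(responses, dict):
        responses = [responses[d] for d in DOMAINS]
    codes = np.asarray(list(responses))
    if codes.shape != (len(DOMAINS),):
        raise ValueError(f"expected {len(DOMAINS)} responses, got shape {codes.shape}")
    _validate_codes(codes)
    return DisabilityProfile(threshold, tuple(bool(c >= cut) for c in codes))


def classify_members(members: pd.DataFrame, threshold: str) -> pd.DataFrame:
    """Vectorised :func:`classify_member` over a member table.

    Requires the six ``wg_*`` columns; returns a copy with boolean columns
    ``dis_<domain>_<threshold>``, ``disabled_<threshold>``,
    ``n_domains_<threshold>`` and ``multiplicity_<threshold>`` appended.
    """
    cut = check_threshold(threshold)
    missing = [c for c in WG_COLUMNS if c not in members.columns]
    if missing:
        raise ValueError(f"member table is missing WG columns: {missing}")
    codes = members[list(WG_COLUMNS)].to_numpy()
    if np.isnan(codes.astype(float)).any():
        raise ValueError("missing WG responses; impute explicitly before classifying")
    _validate_codes(codes)
    out = members.copy()
    flags = codes >= cut
    for j, d in enumerate(DOMAINS):
        out[f"dis_{d}_{threshold}"] = flags[:, j]
    n = flags.sum(axis=1)
    out[f"n_domains_{threshold}"] = n
    out[f"disabled_{threshold}"] = n >= 1
    out[f"multiplicity_{threshold}"] = np.select(
        [n == 0, n == 1], ["none", "single"], default="multiple"
    )
    return out


def household_disability(members: pd.DataFrame, threshold: str) -> pd.DataFrame:
    """Aggregate member classifications to household-level flags.

    ``members`` must already carry the ``dis_*_<threshold>`` columns from
    :func:`classify_members` plus ``household_id``. A household is flagged
    in a domain when any member is.

    Returns one row per household: ``hh_<domain>_<threshold>`` booleans,
    ``hh_disabled_<threshold>``, ``hh_n_domains_<threshold>`` (count of
    distinct flagged domains across members) and
    ``hh_multiplicity_<threshold>`` (the most-affected member's status:
    none < single < multiple).
    """
    if members.empty:
        raise ValueError("empty member table")
    cols = [f"dis_{d}_{threshold}" for d in DOMAINS]
    missing = [c for c in cols if c not in members.columns]
    if missing:
        raise ValueError(f"run classify_members first; missing {missing}")
    grp = members.groupby("household_id", sort=True)[cols].any()
    grp.columns = [f"hh_{d}_{threshold}" for d in DOMAINS]
    n = grp.to_numpy().sum(axis=1)
    grp[f"hh_n_domains_{threshold}"] = n
    grp[f"hh_disabled_{threshold}"] = n >= 1
    member_n = members[cols].to_numpy().sum(axis=1)
    max_n = (
        pd.Series(member_n, index=members["household_id"].to_numpy())
        .groupby(level=0)
        .max()
        .reindex(grp.index)
        .to_numpy()
    )
    grp[f"hh_multiplicity_{threshold}"] = np.select(
        [max_n == 0, max_n == 1], ["none", "single"], default="multiple"
    )
    return grp.reset_index()


@dataclass
class ProfileDistribution:
    """Single/multiple disability composition at one threshold (Table-1 style).

    ``multiple_with_domain`` shares use the count of multiple-disability
    members as denominator; because domains overlap they need not sum to 100.
    """

    threshold: str
    n_disabled: float
    single_share: float = np.nan
    multiple_share: float = np.nan
    single_by_domain: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    multiple_with_domain: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def empty(self) -> bool:
        return self.n_disabled == 0


def profile_distribution(
    members: pd.DataFrame, threshold: str, weights=None
) -> ProfileDistribution:
    """Tabulate the single vs multiple disability profile among the disabled.

    Shares are percentages. Among singles, the per-domain shares partition
    the singles; among multiples, each domain's share is the (weighted)
    fraction of multiple-disability members reporting that domain, so the
    shares may exceed 100 in total.
    """
    cols = [f"dis_{d}_{threshold}" for d in DOMAINS]
    if any(c not in members.columns for c in cols):
        members = classify_members(members, threshold)
    w = np.ones(len(members)) if weights is None else np.asarray(weights, dtype=float)
    n_dom = members[cols].to_numpy().sum(axis=1)
    disabled = n_dom >= 1
    total = float(w[disabled].sum())
    if total == 0:
        return ProfileDistribution(threshold, 0.0)
    single = n_dom == 1
    multiple = n_dom >= 2
    w_single, w_multiple = float(w[single].sum()), float(w[multiple].sum())
    single_by = pd.Series(
        {
            d: 100.0 * float(w[single & members[f"dis_{d}_{threshold}"]].sum()) / w_single
            if w_single
            else np.nan
            for d in DOMAINS
        }
    )
    multi_with = pd.Series(
        {
            d: 100.0
            * float(w[multiple & members[f"dis_{d}_{threshold}"]].sum())
            / w_multiple
            if w_multiple
            else np.nan
            for d in DOMAINS
        }
    )
    return ProfileDistribution(
        threshold=threshold,
        n_disabled=total,
        single_share=100.0 * w_single / total,
        multiple_share=100.0 * w_multiple / total,
        single_by_domain=single_by,
        multiple_with_domain=multi_with,
    )


class WashingtonGroupClassifier(BaseEstimator, TransformerMixin):
    """Transformer adding WG-SS disability classifications to a member table.

    Parameters
    ----------
    thresholds : tuple of {"lower", "higher"}
        Severity thresholds to classify at (both by default).
    """

    def __init__(self, thresholds: tuple[str, ...] = ("lower", "higher")):
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y=None):  # stateless; validates input
        for t in self.thresholds:
            check_threshold(t)
        _validate_codes(X[list(WG_COLUMNS)].to_numpy())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X
        for t in self.thresholds:
            out = classify_members(out, t)
        return out

    def household_flags(self, members: pd.DataFrame) -> pd.DataFrame:
        """Member table -> one row per household with union flags at every threshold."""
        out = self.transform(members)
        frames = [household_disability(out, t) for t in self.thresholds]
        merged = frames[0]
        for f in frames[1:]:
            merged = merged.merge(f, on="household_id")
        return merged
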