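"""Synthetic household-survey generator with known embedded extra costs.

Every stage of the analysis is verifiable by parameter recovery: the
generator embeds a known extra-cost structure (a fraction of quintile-mean
normalized expenditure diverted by households with a moderate/severe
disability) into a latent standard-of-living index, then realizes the
index as asset data. The emitted truth table is the multiplier table the
SOL estimator should recover.

Reproducibility: all randomness flows from one root seed through named
substreams (households, members, assets, goods-and-services), so identical
configs give byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assets import AssetVector
from .config import SimConfig
from .domains import DOMAINS, WG_COLUMNS, age_band
from .sol import MultiplierTable, assign_quintiles, normalize_expenditure
from .wg import classify_members, household_disability


@dataclass
class SyntheticSurvey:
    """Generated survey tables plus the embedded ground truth."""

    households: pd.DataFrame
    members: pd.DataFrame
    respondents: pd.DataFrame
    cost_items: pd.DataFrame
    truth: MultiplierTable
    config: SimConfig = field(repr=False, default=None)

    def write_csvs(self, out_dir) -> dict:
        """Write the four tables plus the truth table as CSV; returns paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("households", self.households),
            ("members", self.members),
            ("respondents", self.respondents),
            ("cost_items", self.cost_items),
            ("truth", self.truth.df),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


def generate_asset_vector(
    latent_index: float,
    mode: str,
    rng: np.random.Generator,
    n_items: int = 16,
    n_dwellings: int = 4,
    item_noise_sd: float = 10.0,
) -> AssetVector:
    """Realize one household's asset data from its latent index.

    ``linear_index`` carries the clamped latent index directly
    (:func:`discost.assets.compute_index` recovers it exactly);
    ``item_threshold`` sets component j owned iff
    latent + noise_j > threshold_j, with thresholds evenly spread over the
    0-100 index range, so the equal-weight index is monotone in the latent
    index in expectation.
    """
    if mode == "linear_index":
        return AssetVector(direct_index=float(np.clip(latent_index, 0.0, 100.0)))
    if mode != "item_threshold":
        raise ValueError(f"unknown asset mode {mode!r}")
    j = n_items + n_dwellings
    thresholds = 100.0 * (np.arange(j) + 0.5) / j
    noise = rng.normal(0.0, item_noise_sd, size=j)
    owned = (latent_index + noise > thresholds).astype(int)
    return AssetVector(items=owned[:n_items], dwellings=owned[n_items:])


def _asset_columns(latent: np.ndarray, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.asset_mode == "linear_index":
        return pd.DataFrame({"asset_index": np.clip(latent, 0.0, 100.0)})
    j = config.n_asset_items + config.n_dwelling_items
    thresholds = 100.0 * (np.arange(j) + 0.5) / j
    noise = rng.normal(0.0, config.item_noise_sd, size=(len(latent), j))
    owned = (latent[:, None] + noise > thresholds[None, :]).astype(int)
    cols = [f"asset_{i + 1:02d}" for i in range(config.n_asset_items)] + [
        f"dwell_{i + 1:02d}" for i in range(config.n_dwelling_items)
    ]
    return pd.DataFrame(owned, columns=cols)


def generate_gs_costs(
    config: SimConfig, respondents: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw goods-and-services cost-item records for a respondent table.

    ``respondents`` carries ``respondent_id`` and boolean ``dis_<domain>``
    columns. Disability-serving catalog entries generate records only for
    respondents flagged in a matching domain; ``essential_needs`` entries
    apply to everyone. Purchase prices and recurring costs are drawn
    log-normally around the catalog means.
    """
    from .domains import GS_CATEGORIES

    n = len(respondents)
    frames = []
    for tpl in config.gs_item_catalog:
        if tpl.category not in GS_CATEGORIES:
            raise ValueError(f"unknown cost category {tpl.category!r}")
        if tpl.category == "essential_needs" or not tpl.domains:
            eligible = np.ones(n, dtype=bool)
        else:
            eligible = np.zeros(n, dtype=bool)
            for d in tpl.domains:
                eligible |= respondents[f"dis_{d}"].to_numpy(bool)
        take = eligible & (rng.random(n) < tpl.prob)
        k = int(take.sum())
        if k == 0:
            continue

        def draw(mean: float) -> np.ndarray:
            if mean <= 0:
                return np.zeros(k)
            s = tpl.price_sigma
            return rng.lognormal(np.log(mean) - s**2 / 2.0, s, size=k)

        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": respondents.loc[take, "respondent_id"].to_numpy(),
                    "item": tpl.item,
                    "category": tpl.category,
                    "purchase_price": draw(tpl.price_mean),
                    "lifespan_months": float(tpl.lifespan_months),
                    "recurring_cost": draw(tpl.recurring_mean),
                    "frequency_per_month": float(tpl.frequency_per_month),
                    "disability_specific": tpl.disability_specific,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "respondent_id",
                "item",
                "category",
                "purchase_price",
                "lifespan_months",
                "recurring_cost",
                "frequency_per_month",
                "disability_specific",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def generate_population(config: SimConfig) -> SyntheticSurvey:
    """Generate the full synthetic survey: households, members, GS records, truth.

    The household latent index is
    S* = k + alpha*(Y - C) + gamma'X + eps with C the embedded diverted
    expenditure (see :class:`discost.config.SimConfig`), so the SOL
    regression's estimand in each (domain, quintile) stratum equals the
    configured cost fraction exactly.
    """
    config.validate()
    if config.n_households < 30:
        warnings.warn("n_households < 30: strata may be empty", stacklevel=2)
    ss = np.random.SeedSequence(config.seed)
    rng_hh, rng_mem, rng_asset, rng_gs = (np.random.default_rng(s) for s in ss.spawn(4))
    n = config.n_households

    # --- households -------------------------------------------------------
    region_ids = np.array([r for r, _ in config.regions])
    region_lines = np.array([line for _, line in config.regions])
    ridx = rng_hh.integers(len(region_ids), size=n)
    mu, sigma = config.expenditure_lognormal
    households = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:07d}" for i in range(n)],
            "region": region_ids[ridx],
            "poverty_line": region_lines[ridx],
            "weight": 1.0,
            "exp_pc": rng_hh.lognormal(mu, sigma, size=n),
            "hh_size": 1 + rng_hh.poisson(max(config.mean_household_size - 1, 0.0), size=n),
            "urban": (rng_hh.random(n) < config.urban_share).astype(int),
            "head_age": rng_hh.uniform(20, 80, size=n),
            "head_sex": rng_hh.integers(0, 2, size=n),
            "head_edu": rng_hh.choice(len(config.head_edu_probs), size=n, p=config.head_edu_probs),
        }
    )

    # --- members ----------------------------------------------------------
    sizes = households["hh_size"].to_numpy()
    total = int(sizes.sum())
    hh_rep = np.repeat(np.arange(n), sizes)
    pos = np.concatenate([np.arange(s) for s in sizes]) if n else np.array([], int)
    is_head = pos == 0
    ages = rng_mem.uniform(0, 80, size=total)
    sexes = rng_mem.integers(0, 2, size=total)
    ages[is_head] = households["head_age"].to_numpy()[hh_rep[is_head]]
    sexes[is_head] = households["head_sex"].to_numpy()[hh_rep[is_head]]
    members = pd.DataFrame(
        {
            "member_id": [f"M{i + 1:08d}" for i in range(total)],
            "household_id": households["household_id"].to_numpy()[hh_rep],
            "is_head": is_head.astype(int),
            "age": ages,
            "sex": sexes,
            "activity": rng_mem.choice(
                ["working", "student", "homemaker", "other"], size=total, p=(0.45, 0.2, 0.2, 0.15)
            ),
        }
    )
    for d in DOMAINS:
        members[f"wg_{d}"] = rng_mem.choice(4, size=total, p=config.domain_prevalence[d])

    # --- embedded cost and latent index ----------------------------------
    classified = classify_members(members, config.cost_threshold)
    hh_flags = household_disability(classified, config.cost_threshold)
    hh = households.merge(hh_flags, on="household_id", how="left")
    y = normalize_expenditure(hh["exp_pc"], hh["poverty_line"])
    quintile = assign_quintiles(y)
    y = np.asarray(y, dtype=float)
    mean_y_q = {q: float(y[quintile == q].mean()) for q in np.unique(quintile)}
    frac = np.zeros(n)
    for d in DOMAINS:
        flag = hh[f"hh_{d}_{config.cost_threshold}"].to_numpy(bool)
        fd = np.array([config.true_cost_fraction.get((d, q), 0.0) for q in quintile])
        frac = np.where(flag, np.maximum(frac, fd), frac)
    c = frac * np.array([mean_y_q[q] for q in quintile])
    x_effect = sum(
        g * hh[name].to_numpy(float) for name, g in config.gamma_true.items() if name in hh
    )
    latent = (
        config.k_true
        + config.alpha_true * (y - c)
        + x_effect
        + rng_asset.normal(0.0, config.noise_sd, size=n)
    )
    households = pd.concat([households, _asset_columns(latent, config, rng_asset)], axis=1)

    # --- truth table ------------------------------------------------------
    truth = MultiplierTable.from_cells(
        {k: 100.0 * v for k, v in config.true_cost_fraction.items()},
        threshold=config.cost_threshold,
    )

    # --- goods-and-services subsample ------------------------------------
    pool_dis = classified.index[classified[f"disabled_{config.cost_threshold}"]].to_numpy()
    pool_non = classified.index[~classified[f"disabled_{config.cost_threshold}"]].to_numpy()
    take_dis = rng_gs.choice(pool_dis, size=min(config.gs_n_disabled, len(pool_dis)), replace=False)
    take_non = rng_gs.choice(pool_non, size=min(config.gs_n_controls, len(pool_non)), replace=False)
    chosen = classified.loc[np.concatenate([take_dis, take_non])]
    ndom = chosen[f"n_domains_{config.cost_threshold}"].to_numpy()
    single_domain = np.full(len(chosen), "none", dtype=object)
    for d in DOMAINS:
        single_domain[
            (ndom == 1) & chosen[f"dis_{d}_{config.cost_threshold}"].to_numpy(bool)
        ] = d
    respondents = pd.DataFrame(
        {
            "respondent_id": chosen["member_id"].to_numpy(),
            "household_id": chosen["household_id"].to_numpy(),
            "age": chosen["age"].to_numpy(),
            "age_band": [age_band(a) for a in chosen["age"]],
            "disability_type": np.where(ndom >= 2, "multiple", single_domain),
        }
    )
    for d in DOMAINS:
        respondents[f"dis_{d}"] = chosen[f"dis_{d}_{config.cost_threshold}"].to_numpy(bool)
    cost_items = generate_gs_costs(config, respondents, rng_gs)

    members_out = members[
        ["member_id", "household_id", "is_head", "age", "sex", "activity", *WG_COLUMNS]
    ]
    return SyntheticSurvey(
        households=households,
        members=members_out,
        respondents=respondents,
        cost_items=cost_items,
        truth=truth,
        config=config,
    )
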