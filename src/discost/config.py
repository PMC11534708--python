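"""Simulation configuration: the generative model's parameters.

The defaults emulate the statistical shape of an Indonesian national
socio-economic household survey round: log-normal per-capita expenditure,
regional poverty lines around IDR 350-550 thousand per person per month,
WG-SS response prevalences concentrated on "no difficulty" with seeing and
walking the most common difficulties, and a latent standard-of-living index
from which disability households divert a known fraction of expenditure
(the ground-truth extra-cost multiplier, spanning roughly 5-22% and rising
with expenditure quintile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

from .domains import DOMAINS, GS_CATEGORIES, QUINTILES


def _default_regions() -> tuple:
    lines = (362000, 391000, 402000, 425250, 431000, 455000, 472000, 489000, 512000, 547000)
    return tuple((f"R{i + 1:02d}", float(v)) for i, v in enumerate(lines))


def _default_prevalence() -> dict:
    # (none, some, a_lot, cannot); moderate+severe mass per domain 0.5-1.5%,
    # seeing/walking most prevalent, echoing national profile tables.
    return {
        "seeing": (0.940, 0.045, 0.012, 0.003),
        "hearing": (0.966, 0.025, 0.007, 0.002),
        "walking": (0.945, 0.040, 0.011, 0.004),
        "remembering": (0.966, 0.026, 0.006, 0.002),
        "communicating": (0.978, 0.016, 0.004, 0.002),
        "selfcare": (0.982, 0.013, 0.003, 0.002),
    }


def _default_cost_fraction() -> dict:
    # per-domain linear schedule over quintiles spanning ~5-22%
    span = {
        "seeing": (0.05, 0.22),
        "hearing": (0.08, 0.22),
        "walking": (0.06, 0.20),
        "remembering": (0.08, 0.19),
        "communicating": (0.09, 0.17),
        "selfcare": (0.07, 0.18),
    }
    out = {}
    for d, (lo, hi) in span.items():
        for q in QUINTILES:
            out[(d, q)] = lo + (hi - lo) * (q - 1) / 4
    return out


@dataclass(frozen=True)
class CostItemTemplate:
    """Catalog entry from which GS cost-item records are drawn.

    ``domains`` lists the functional domains the item serves; an
    ``essential_needs`` item applies to every respondent regardless of
    disability. ``prob`` is the probability that a matching respondent
    reports the item. Prices are drawn log-normally around ``price_mean``.
    """

    item: str
    category: str
    domains: tuple[str, ...] = ()
    price_mean: float = 0.0
    price_sigma: float = 0.3
    lifespan_months: float = 0.0
    recurring_mean: float = 0.0
    frequency_per_month: float = 0.0
    prob: float = 1.0
    disability_specific: bool = True

    def __post_init__(self):
        if self.category not in GS_CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        unknown = set(self.domains) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains in catalog entry {self.item!r}: {unknown}")
        if not 0 <= self.prob <= 1:
            raise ValueError("prob must be in [0,1]")

    def mean_monthly_equivalent(self) -> float:
        """Expected monthly cost of the item when reported (catalog arithmetic)."""
        base = self.price_mean / self.lifespan_months if self.lifespan_months > 0 else self.price_mean
        return base + self.recurring_mean * self.frequency_per_month


def _default_catalog() -> tuple[CostItemTemplate, ...]:
    c = CostItemTemplate
    return (
        c("wheelchair", "assistive_devices", ("walking",), 2_500_000, 0.3, 60, 20_000, 1.0, 0.6),
        c("hearing_aid", "assistive_devices", ("hearing",), 3_000_000, 0.4, 48, 30_000, 1.0, 0.5),
        c("screen_reader", "assistive_devices", ("seeing",), 1_200_000, 0.4, 36, 0, 0, 0.35),
        c("white_cane", "assistive_devices", ("seeing",), 150_000, 0.3, 24, 0, 0, 0.5),
        c("incontinence_supplies", "assistive_devices", ("selfcare",), 0, 0.3, 0, 10_000, 30, 0.7),
        c("home_modification", "special_accommodation", ("walking", "selfcare"), 1_500_000, 0.5, 120, 0, 0, 0.3),
        c("accessible_data_plan", "special_accommodation", ("seeing", "hearing", "communicating"), 0, 0.3, 0, 100_000, 1.0, 0.5),
        c("sign_interpreter", "human_assistance", ("hearing", "communicating"), 0, 0.3, 0, 150_000, 4.0, 0.4),
        c("caregiver", "human_assistance", ("selfcare", "remembering", "walking"), 0, 0.3, 0, 50_000, 20.0, 0.5),
        c("accessible_taxi", "commute_travel", DOMAINS, 0, 0.3, 0, 40_000, 12.0, 0.6),
        c("intercity_trip", "interstate_travel", DOMAINS, 0, 0.3, 0, 250_000, 0.5, 0.3),
        c("food_staples", "essential_needs", (), 0, 0.2, 0, 400_000, 1.0, 1.0, False),
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic household survey.

    The latent standard-of-living model is
        S* = k + alpha * (Y - C) + gamma' X + eps,  eps ~ N(0, noise_sd^2)
    with Y the poverty-line-normalized per-capita expenditure and C the
    household's diverted expenditure: ``true_cost_fraction[(domain, q)]``
    times the mean Y of quintile q, for households with a moderate/severe
    (higher-threshold) member in that domain, taking the maximum over the
    flagged domains. ``asset_mode="linear_index"`` carries S* (clamped to
    0-100) directly as the asset index, making the SOL estimand exactly the
    configured fraction; ``item_threshold`` realizes binary ownership
    indicators whose equal-weight index rises monotonically with S*.
    """

    n_households: int = 315_672
    seed: int = 0
    regions: tuple = field(default_factory=_default_regions)
    expenditure_lognormal: tuple[float, float] = (math.log(850_000), 0.55)
    domain_prevalence: dict = field(default_factory=_default_prevalence)
    true_cost_fraction: dict = field(default_factory=_default_cost_fraction)
    alpha_true: float = 6.0
    gamma_true: dict = field(
        default_factory=lambda: {
            "hh_size": -1.2,
            "urban": 6.0,
            "head_age": 0.04,
            "head_sex": 0.5,
            "head_edu": 2.0,
        }
    )
    k_true: float = 10.0
    noise_sd: float = 8.0
    asset_mode: str = "linear_index"
    n_asset_items: int = 16
    n_dwelling_items: int = 4
    item_noise_sd: float = 10.0
    mean_household_size: float = 3.9
    urban_share: float = 0.574
    head_edu_probs: tuple = (0.30, 0.35, 0.25, 0.10)
    cost_threshold: str = "higher"
    gs_n_disabled: int = 80
    gs_n_controls: int = 8
    gs_item_catalog: tuple = field(default_factory=_default_catalog)

    def validate(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.asset_mode not in ("linear_index", "item_threshold"):
            raise ValueError(f"unknown asset_mode {self.asset_mode!r}")
        if not self.regions or any(line <= 0 for _, line in self.regions):
            raise ValueError("poverty lines must be positive")
        if set(self.domain_prevalence) != set(DOMAINS):
            raise ValueError("domain_prevalence must cover exactly the six WG domains")
        for d, p in self.domain_prevalence.items():
            p = tuple(p)
            if len(p) != 4 or any(not 0 <= x <= 1 for x in p):
                raise ValueError(f"prevalence for {d} must be four probabilities in [0,1]")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"prevalence for {d} must sum to 1 (got {sum(p)})")
        for (d, q), f in self.true_cost_fraction.items():
            if d not in DOMAINS or q not in QUINTILES:
                raise ValueError(f"true_cost_fraction key ({d}, {q}) out of range")
            if f < 0:
                raise ValueError("true_cost_fraction values must be >= 0")
        if self.noise_sd < 0 or self.item_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.gs_item_catalog:
            raise ValueError("gs_item_catalog must be non-empty")

    # ------------------------------------------------------------------
    # (de)serialization for the CLI's structured config file

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [[r, float(line)] for r, line in self.regions]
        d["domain_prevalence"] = {k: list(v) for k, v in self.domain_prevalence.items()}
        d["true_cost_fraction"] = {
            dom: {f"Q{q}": self.true_cost_fraction[(dom, q)] for q in QUINTILES if (dom, q) in self.true_cost_fraction}
            for dom in sorted({k[0] for k in self.true_cost_fraction})
        }
        d["gs_item_catalog"] = [asdict(t) | {"domains": list(t.domains)} for t in self.gs_item_catalog]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = tuple((r, float(line)) for r, line in d["regions"])
        if "domain_prevalence" in d:
            d["domain_prevalence"] = {k: tuple(v) for k, v in d["domain_prevalence"].items()}
        if "true_cost_fraction" in d and d["true_cost_fraction"] and not isinstance(
            next(iter(d["true_cost_fraction"])), tuple
        ):
            flat = {}
            for dom, byq in d["true_cost_fraction"].items():
                for ql, f in byq.items():
                    flat[(dom, int(str(ql).lstrip("Q")))] = float(f)
            d["true_cost_fraction"] = flat
        if "gs_item_catalog" in d:
            d["gs_item_catalog"] = tuple(
                t if isinstance(t, CostItemTemplate) else CostItemTemplate(**{**t, "domains": tuple(t.get("domains", ()))})
                for t in d["gs_item_catalog"]
            )
        if "expenditure_lognormal" in d:
            d["expenditure_lognormal"] = tuple(d["expenditure_lognormal"])
        if "head_edu_probs" in d:
            d["head_edu_probs"] = tuple(d["head_edu_probs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
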