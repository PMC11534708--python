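# Methods

## The standard-of-living model

The SOL (expenditure-equivalence) approach identifies the extra cost of
disability from the wedge between material well-being and expenditure.
For household *i* in a stratum,

S_i = α Y_i + β D_i + γ′X_i + k + ε_i

where *S* is a 0–100 asset index, *Y* = per-capita expenditure divided by
the household's regional poverty line (a dimensionless welfare ratio that
removes regional cost-of-living differences), *D* indicates a member with
the stratum's disability type at the stratum's severity threshold, and *X*
are demographic controls. The extra cost is E = −β/α: the extra normalized
expenditure needed to close the standard-of-living gap. Its standard error
uses the first-order delta method,

Var(E) = Var(β)/α² + β²Var(α)/α⁴ − 2β·Cov(α,β)/α³,

and E is reported as a percent of the stratum's mean welfare ratio
(100·E/mean Y). An estimate is only meaningful when α > 0 (the index must
rise with expenditure); such cells, unestimable strata, and cells with a
two-sided p-value on β above 10% are blanked.

**Stratification.** Regressions run separately by disability type ×
expenditure quintile × threshold. The disability side of each stratum is
restricted to households whose *only* flagged type is the stratum's type
(single-type design); the comparison side is households with no disability
at the threshold. Multi-type households are therefore never used in SOL
estimation — their costs enter through the poverty-adjustment policy rule
instead (highest multiplier among the flagged types), because a
type-by-type regression design cannot identify a multiple-disability
coefficient. Each threshold is estimated in its own regression; the two
columns of the multiplier table are not pooled.

**Quintiles.** Weighted quintiles of Y use the weighted ECDF
F(y) = Σ{w_j : y_j ≤ y}/Σw_j; an observation lands in quintile ⌈5F⌉, with
exact ties at a cut point assigned to the lower quintile after a stable
sort, so outputs are deterministic.

**Levels vs logs.** The default uses Y in levels (the welfare-ratio
reading of poverty-line-adjusted expenditure). A log mode is provided; in
log mode E is in log points and the percent multiplier is 100·(exp(E)−1).

**Controls.** Default household-level controls: household size, urban
indicator, head age, head sex, head education band. The list is
configuration, not code; collinear controls are dropped with a warning.
Estimation is unweighted by default with optional survey weights (WLS).

## The asset index

index = 100 · Σ w_j x_j / Σ w_j over binary ownership indicators (16 asset
items by default) plus dwelling-quality indicators, so 0 means owning
nothing and 100 everything. Weights default to equal — no weighting scheme
is imposed by the data, and equal weights keep the 0–100 contract exact
and make E invariant to rescaling all weights (tested end to end). A
first-principal-component weighting is available as a sensitivity mode;
its loadings are oriented so ownership raises the index and clipped at
zero.

## Poverty adjustment

Each household's line becomes line·(1+m). The multiplier m is 0 for
no-disability households; for single-type households the type's bottom-40%
multiplier; for multi-type households the maximum over flagged types.
"Bottom 40%" is estimated as a pooled Q1∪Q2 stratum per type (re-using the
stratum regression) rather than averaging the Q1 and Q2 cells — pooling
uses all bottom-40 observations in one fit; the per-quintile source is
selectable. Blank cells contribute zero by default, which understates
adjusted poverty (conservative); an exclude-household rule is available.
Headcounts compare per-capita expenditure to the (adjusted) line at the
household level; person-weighted rates are available through the weight
column. Reported groups are no-disability, any-difficulty (lower
threshold) and its moderate/severe subset (higher threshold), so the
nesting of the two disabled groups is explicit.

## Goods-and-services costing

Each cost-item record carries a purchase price, a lifespan in months, a
recurring unit cost and a monthly frequency. Monthly equivalent = price /
lifespan (straight-line amortization; lifespan 0 marks a non-durable whose
price counts in the month of purchase) + recurring × frequency. A one-off
mode that charges durables fully in the purchase month is available.
Per-person totals sum categories; the disability-specific subtotal sums
flagged items only. Summaries use the linear-interpolation quantile
(numpy's default) so median and P75 are reproducible; median ≤ P75 by
construction. Affordability is assessed two ways: cost − wage gaps and
cost/wage ratios per statistic against a minimum-wage floor (strict
exceedance flags), and the weighted-ECDF percentile of a cost in the
per-capita expenditure distribution (only people above that percentile
out-spend the cost). P75 and the percentile are computed over persons, not
households. The eight field-survey disability types map to summary groups
via a configurable table (default: the six WG domains plus "multiple" and
"none").

## The synthetic survey generator

The generator emulates the statistical shape the analyses assume, with a
known embedded answer:

* per-capita expenditure log-normal (default median ≈ IDR 850k/person/
  month, σ = 0.55) over ten regions with poverty lines IDR 362k–547k;
* member WG-SS responses drawn independently per domain from configurable
  four-level probabilities (defaults put ~0.5–1.5% of persons at
  moderate/severe per domain, seeing and walking most prevalent);
* households: size 1 + Poisson (mean 3.9), urban share 57.4%, head age
  20–80, head sex, four education bands;
* a latent index S\* = k + α(Y − C) + γ′X + ε with ε ~ N(0, noise_sd²),
  noise_sd = 8 index points by default;
* the embedded cost C = fraction(domain, quintile) × mean Y of the
  household's quintile, applied to households with a moderate/severe
  member in the domain, maximum over flagged domains. Default fractions
  rise linearly across quintiles within each domain and span 5–22%. Since
  the diversion is written as Y_eff = Y − C, the stratum estimand is
  exactly the configured fraction: β = −αC.

Only higher-threshold (moderate/severe) households divert expenditure;
households whose worst difficulty is "some" divert nothing. The emitted
truth table therefore applies to the higher threshold, and lower-threshold
estimates are naturally attenuated mixtures — qualitatively matching the
smaller any-difficulty multipliers seen in practice.

**Asset realization.** `linear_index` mode carries clip(S\*, 0, 100)
directly as an `asset_index` column that the index computation passes
through unchanged. A finite set of binary items cannot encode an arbitrary
real exactly, so this pass-through is the mode in which recovery is sharp;
it is the default and the diagnostic mode for oracle tests.
`item_threshold` mode realizes 16 asset + 4 dwelling binary indicators,
item j owned iff S\* + noise_j exceeds a threshold spread evenly over
0–100, giving a realistic binary table whose equal-weight index is
monotone in S\* in expectation.

**GS records.** A catalog of item templates (category, serving domains,
price/lifespan/recurring/frequency, reporting probability) generates
records for a subsample of 80 disabled + 8 non-disabled respondents by
default; disability-serving items only reach respondents flagged in a
matching domain, essential-needs items reach everyone, and prices draw
log-normally around catalog means.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real data: survey sampling design (PSU
strata, nonresponse, weights ≠ 1), measurement error in expenditure,
correlation between domains within a person, correlation between
disability and expenditure or household composition, and any behavioural
response of spending to disability beyond the mechanical diversion. The
recovery results certify the estimator, not the substantive magnitudes.

## Numerical and design choices

* All randomness flows from one root seed through named substreams
  (households, members, assets, GS), so identical configs give
  byte-identical tables.
* Degenerate strata (no variation in D, or fewer observations than
  coefficients + 2) raise a typed error that maps to a BLANK cell.
* The compensating-expenditure oracle is regression-free: it interpolates
  each group's index-versus-Y profile and solves
  S_dis(y₁) = S_nodis(y₁ − Δ) at several quantiles of the disability
  group's Y, taking the median Δ. With noiseless linear data it equals
  −β/α to solver precision and is used as an independent check.
* No multiple-testing correction is applied to the 10% blanking rule; with
  zero embedded cost the share of non-blank cells is itself a calibration
  check (≈10%).
* Quintile ties break downward; quantiles interpolate linearly; the
  exceedance flag against the wage floor is strict.
* Problem sizes used in the shipped checks: oracle equivalence on a
  20,000-household noiseless survey (30 strata); multiplier recovery on a
  200,000-household survey; null calibration over 240 strata from four
  20,000-household surveys; the bootstrap comparison on one stratum with
  1,000 resamples; the affordability check on a 100,000-draw expenditure
  sample.

## Known limitations

* The asset index treats components symmetrically; no item-response or
  PCA-by-default weighting, no urban/rural-specific item lists.
* Multiple-disability extra costs are handled only by the max-over-types
  policy rule, which field evidence suggests understates them.
* The bundled example multiplier table is printed output of a published
  study; its blank pattern and bottom-40 fallback (Q1 cell when
  populated, else Q2) are conventions of this package, not of the source.
* GS summaries assume the cost-item file is complete per respondent;
  under-reported needs (notably assistive devices) pass through
  unadjusted.
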