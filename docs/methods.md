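# Methods

## The satisfaction index

The index is a product of eight unitless factors (gender, age, environment,
infection, complication, protocol, innovation, pain), each equal to 1.0 at
its reference level; the two continuous factors are affine, `1 + 0.1·(age/10)`
and `1 + 0.1·pain`. A multiplicative form means every risk factor scales the
whole score: a complication doubles the total regardless of the patient's
other attributes, and the decomposition `total = Π factors` holds exactly
(asserted to 1e-12 in double precision). Higher totals mean lower
satisfaction; the bands are high (≤ 1.5), moderate (1.5, 3.0], low (> 3.0),
with both boundaries belonging to the better band, matching the strict
">" readings of the published band definitions.

Choices where the published description is silent:

* **Age** enters as a continuous value (fractional decades allowed); the
  formula divides by 10 without truncation, so nothing suggests binning.
* **Pain** is accepted on 0–10. The factor formula is well defined at 0 and
  the international numeric rating scale includes it, even though the
  scale is sometimes described as 1–10.
* **Missing algorithm inputs.** Two policies: `strict` (default) skips the
  record and reports which fields were missing; `neutral` substitutes the
  neutral factor 1.0 for the missing field and logs it. Neither invents an
  imputation model, which would smuggle assumptions into a published
  constant set.
* All constants are configurable (`FactorWeights`), because the shipped
  values were tuned on one hospital's internal data and other sites will
  retune them.

## Quality control

A questionnaire is discarded iff its fraction of unanswered in-scope items
strictly exceeds the threshold (default 0.20 — "over 20%"). The in-scope
set defaults to every item except the administrative year/ward columns.
One refinement is essential: the items that only exist for operated
respondents (Q2 and the five clinical algorithm inputs) are removed from a
record's in-scope set when the respondent answers "no" to the surgery
question. Without this, every non-operated respondent would carry six
structurally blank items (50% of the scope) and be discarded wholesale,
which contradicts the design in which roughly a quarter of retained
respondents are non-operated. The literal all-fields rule remains available
(`skip_inapplicable=False`).

Logical-consistency checks (Q2 answered without surgery; clinical items
answered without surgery) flag records separately; the `analyze` command
drops flagged records by default (`--keep-inconsistent` to retain).

## Trend statistics

* **Paired year-pair tests.** The published paired-test rows are jointly
  consistent only with six paired units per year (df = 5), but the unit is
  not stated. The pipeline aggregates per-record scores into six per-year
  group means — by default a ward clustering that merges the two
  general-surgery wards and the two orthopedics wards (8 wards → 6 units);
  a positional `month_block` split is available for cohorts whose ward
  labels differ. Differences are earlier-minus-later year, so positive
  means are improvements. `paired_t_from_summary` applies the identical
  formulas to a printed (mean, SD, n) row, so published rows verify
  independently of the grouping choice. The reconstructed 95% CI bounds
  differ from the printed ones only at the 4th decimal, consistent with
  rounding of the printed means/SDs.
* All tests are two-sided at 95% confidence. No multiplicity correction is
  applied across the ten year pairs by default, mirroring the published
  presentation; Bonferroni and Holm are available (`multiple_correction`).
* Chi-square is Pearson's statistic without continuity correction
  (configurable); `auto` contingency testing switches to Fisher's exact
  test for 2×2 tables with any expected count below 5.
* The Shapiro–Wilk gate tests each Likert item; if either rejects
  normality at α = 0.05 (discrete 5-point items virtually always do at
  these sample sizes), the Q2–Q3 association uses Spearman's rank
  correlation with midrank ties, otherwise Pearson.
* Cronbach's alpha uses the definitional form
  `k/(k−1)·(1 − Σ item variances / variance of row sums)` with unbiased
  variances and row-wise deletion.
* ANOVA treats Likert responses as numeric, matching the use of cell means
  in the reported tables; no ordinal model is offered.
* Yearly score summaries use type-7 (linearly interpolated) percentiles
  for the IQR; SD is the unbiased estimator and is reported as missing for
  single-observation years.
* Degenerate inputs (zero within-group variance, zero-margin tables,
  constant samples, zero-variance differences) raise a dedicated
  `DegenerateStatisticError` rather than returning NaN; the pipeline
  converts these into recorded skip reasons.
* Report rounding: means 2 dp, test statistics 3 dp in the CSV outputs;
  `summary.json` keeps full precision.

## Synthetic cohort generator

The generator emulates the study design whose raw data are unavailable:
eight surgical wards × five years, with published ward-by-year
questionnaire counts (3985 total), surgery rates, ward age profiles
(truncated normal on the published 12–96 range, SD 15.8), demographic
shares (male 53.15%; urban/rural 44.47/38.87% with 16.66% nonresponse;
five education levels), ward-by-year Likert target means for both items,
a pooled Q2–Q3 rank-correlation target of 0.51, and 33 grossly incomplete
questionnaires on top (4018 generated).

Mechanics and calibrations:

* **Likert items.** For each cell, a base cutpoint set (−1.5, −0.5, 0.5,
  1.5 in latent SD units) is shifted as a block until the implied
  5-category mean matches the cell target (Brent's method, well under the
  0.01 contract). Cell targets of exactly 5 are clamped to 4.99 with a
  warning — a continuous latent cannot put all mass in one category. The
  (Q2, Q3) pair is a correlated standard-normal latent pair pushed through
  the two cutpoint sets. The latent correlation (0.6929) was calibrated by
  seeded Monte-Carlo bisection (`calibrate_latent_rho`) so the *pooled
  rank correlation* of the discretized, heavily tied items hits 0.51;
  pooling across cells with different means contributes association, which
  is why the latent value is not 0.51.
* **Clinical inputs** have no published values; their defaults are
  calibrated, not observed. Infection, complication and pain follow fixed
  declining trends (infection 5→1%, complication 8→1%, mean pain 2.2→0.2;
  pain is Binomial(10, mean/10)), and a single per-year adoption intensity
  u, shared by personalized protocols and innovative products, is the root
  of the quadratic `(1 − 0.2u)(1 − 0.1u) = target / (demographic · fixed
  clinical expectation)`, solved per year so that the expected mean score
  equals the published yearly means (2.09, 2.16, 1.70, 1.78, 1.50).
  Because factors are generated independently, the expected total
  factorizes exactly, so the calibration is closed-form (the demographic
  expectation uses truncated-normal age means and the ward mix weighted by
  operated counts). Note the published constants leave little room at the
  bottom: with this demographic mix the expected score cannot fall below
  ≈1.36, so the 2023 target of 1.50 forces near-universal personalized
  protocols and innovation use and very low pain — the generator makes that
  corner explicit rather than hiding it. Infeasible targets are clamped to
  u = 1 with a warning.
* **Missingness.** Item nonresponse is injected last at per-field rates
  (residence 16.66% and education 3.56% from the published no-answer
  shares; Q2 at 1 − 2090/2994 ≈ 30.2% for operated respondents, uniform
  because no pattern is published; small rates elsewhere). Injection is
  capped per record at the 20% rule's floor (2 of 12 applicable items for
  operated, 1 of 6 for non-operated) so ordinary records never cross the
  exclusion threshold; the 33 gross records blank strictly more than 20% of
  their applicable items. The exclusion filter therefore retains exactly
  3985 by construction — this is a designed property of the fixture, not an
  empirical finding. The capping shaves a percentage point or two off the
  largest marginal rates; all rates stay within the 3-standard-error
  recovery tolerances.
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw; identical seed + config gives byte-identical CSV output.

`recovery_report` audits a generated cohort against its configuration
(demographic shares, ward age means against the truncated-normal
expectation, per-year surgery rates, per-year Likert means, pooled rank
correlation, yearly score means) at 3-standard-error tolerances computed
from the realized sample sizes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: joint dependence beyond ward/year conditioning
(e.g. age × surgery, sicker-patient nonresponse), informative missingness,
within-year temporal structure, ward-specific clinical rates, or the
published yearly score SDs (0.52 … 0.14), which describe the spread of six
aggregated units rather than of patients and are not targeted. Parameter
recovery on synthetic cohorts validates the pipeline's arithmetic and
calibration, not the hospital's substantive conclusions.

## Problem sizes

The test suite and acceptance script use the full design sizes — 4018
generated questionnaires, 3985 retained, roughly 2100–2900 operated —
since generation and analysis complete in about a second. Simulation-based
checks use 5000 replicates for the paired-t type-I error, 200 for the
Shapiro type-I error, 40,000 draws for latent-correlation re-calibration,
and exhaustive enumeration (~300k tables) for the Fisher oracle.

## Known limitations

* The paired-unit construction (six ward clusters) is one defensible
  reading of an under-specified design; the printed rows are verified via
  the summary-statistic path instead, which is construction-independent.
* The cumulative Likert row is the n-weighted mean of ward cells; an
  unweighted mean of ward means is not offered.
* The exclusion rule's in-scope field set is configurable but the shipped
  default (all items except year/ward, with surgery-conditional items
  dropped for non-operated respondents) is the only set exercised by the
  shipped fixture.
* `neutral` imputation biases totals toward 1.0 for records with missing
  risk factors; it is intended for sensitivity analysis, not estimation.
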