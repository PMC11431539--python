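# postopsat

Postoperative patient-satisfaction scoring and five-year questionnaire trend
analysis.

Hospitals that survey surgical patients routinely face the same analysis
problem: thousands of short questionnaires per year (a surgery indicator and
a couple of 1–5 Likert items), spread over many wards, with substantial item
nonresponse — and a need to say whether satisfaction is actually improving
over time and whether it depends on who the patients are. `postopsat`
packages that workflow for an 8-ward × 5-year surgical-survey design:
quality control, a composite satisfaction index, and the trend statistics,
plus a calibrated synthetic-cohort generator so the entire pipeline can be
exercised and validated without access to any hospital's raw patient data.

It is aimed at hospital quality-management analysts and health-services
researchers working with this kind of survey.

## The satisfaction algorithm

Each operated respondent gets a multiplicative total score built from eight
unitless factors anchored at 1.0:

```
S = f_gender · f_age · f_env · f_infection · f_complication · f_protocol · f_innovation · f_pain
```

with

| factor | levels / formula | default values |
|---|---|---|
| gender | male / female | 1.2 / 1.0 |
| age | 1.0 + 0.1·(age/10) | continuous |
| environment | urban / rural | 1.3 / 1.0 |
| infection | yes / no | 1.5 / 1.0 |
| complication | yes / no | 2.0 / 1.0 |
| protocol | standard / personalized | 1.0 / 0.8 |
| innovation | used / none | 0.9 / 1.0 |
| pain (0–10) | 1.0 + 0.1·pain | continuous |

Factors above 1 encode slower expected recovery; higher totals therefore
mean *lower* satisfaction. The score is banded as **high** (S ≤ 1.5),
**moderate** (1.5 < S ≤ 3.0) or **low** (S > 3.0). All constants live in
`FactorWeights` and can be retuned per site via a config file.

Around the score, the package implements the survey pipeline: a strict
"over 20% unanswered in-scope items" exclusion rule (surgery-only items are
not held against non-operated respondents), logical-consistency flagging,
ward/year Likert summaries, one-way ANOVA with Tukey HSD, chi-square /
Fisher exact tests, all C(5,2) = 10 year-pair paired t-tests on aggregated
scores, a Shapiro–Wilk normality gate that selects Spearman (vs Pearson)
for the Q2–Q3 correlation, and Cronbach's alpha.

## Worked example

```
$ postopsat --log-level ERROR simulate --seed 42 -o sim
wrote 4018 records to sim/cohort.csv (seed 42)
$ postopsat --log-level ERROR analyze -i sim/cohort.csv -o report
analyzed 3985 of 4018 records (33 excluded); report in report
$ postopsat report -i report/summary.json
=== Satisfaction trend report ===
  2019: mean 2.09  sd 0.80  median 1.89  IQR [1.58, 2.33]  (n=421)
  2020: mean 2.14  sd 0.74  median 1.99  IQR [1.65, 2.43]  (n=437)
  2021: mean 1.70  sd 0.48  median 1.64  IQR [1.37, 1.95]  (n=375)
  2022: mean 1.86  sd 0.66  median 1.75  IQR [1.44, 2.08]  (n=334)
  2023: mean 1.48  sd 0.32  median 1.45  IQR [1.27, 1.67]  (n=560)
--- year-pair paired t-tests ---
  2019-2020: diff -0.012  t=-0.233  p=0.825
  ...
  2019-2023: diff +0.592  t=21.739  p=0.000 *
--- Q2-Q3 correlation: spearman rho=0.504 p=5.27e-130 (n=2013)
--- Cronbach's alpha (Q2, Q3): 0.704
```

Reading the output: of 4018 simulated questionnaires, 33 grossly incomplete
ones fail the 20% missingness rule, leaving 3985. The yearly lines summarize
the algorithm score over scored operated respondents (n per year): mean
satisfaction scores fall from 2.09 (moderate band) in 2019 to 1.48 (high
band) in 2023 — i.e. satisfaction improves. Each paired line tests one year
pair on six ward-cluster means; positive differences mean the later year
scored lower (better), and the star marks p < 0.05. The Shapiro gate rejects
normality for the discrete Likert items, so the Q2–Q3 association is
reported as a Spearman correlation (here 0.50).

`postopsat verify-printed` recomputes, from the five-year summary rows
shipped with the package, every internally verifiable published number
(each year-pair t statistic from its mean/SD at n = 6, the count totals,
the overall surgery percentage) and reports expected vs computed.

The same steps are available as library calls: `default_config` /
`generate_cohort`, `apply_exclusion`, `score_dataset`, `run_pipeline`, and
`recovery_report` (configured-vs-empirical audit of a generated cohort).

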