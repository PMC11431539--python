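"""Published five-year study summaries shipped as calibration defaults.

The package emulates a retrospective patient-satisfaction study run on the
eight surgical wards of a large tertiary hospital over 2019-2023.  The raw
questionnaires are not public; what the study released are marginal summary
tables (questionnaire counts, ward age profiles, surgery rates, Likert means,
paired year-pair test rows, yearly algorithm-score summaries).  Those
summaries are reproduced here verbatim and serve two purposes:

* they are the default targets of :mod:`postopsat.synthetic` — synthetic
  cohorts are calibrated so that every marginal below is recovered within
  sampling error;
* :func:`reference_consistency_checks` recomputes every internally
  verifiable number (paired t statistics from their mean/SD columns, count
  totals, the overall surgery percentage) and reports agreement, which is
  the executable audit of the constants themselves.

All numbers are exactly as printed in the study's summary tables; none are
produced by this package.
"""

from __future__ import annotations

from dataclasses import dataclass

YEARS: tuple[int, ...] = (2019, 2020, 2021, 2022, 2023)

#: Short ward identifiers used throughout the package, in study order.
WARDS: tuple[str, ...] = (
    "plastic_surgery",
    "general_surgery_1",
    "general_surgery_2",
    "neurosurgery",
    "ent",
    "orthopedics_1",
    "orthopedics_2",
    "urology",
)

WARD_LABELS: dict[str, str] = {
    "plastic_surgery": "Plastic Surgery, Reconstructive Microsurgery",
    "general_surgery_1": "General Surgery I",
    "general_surgery_2": "General Surgery II",
    "neurosurgery": "Neurosurgery",
    "ent": "ENT",
    "orthopedics_1": "Orthopedics and Trauma I",
    "orthopedics_2": "Orthopedics and Trauma II",
    "urology": "Urology",
}

#: Questionnaires retained per ward and year (columns follow ``YEARS``).
WARD_YEAR_COUNTS: dict[str, tuple[int, ...]] = {
    "plastic_surgery": (112, 143, 95, 68, 78),
    "general_surgery_1": (126, 156, 133, 97, 162),
    "general_surgery_2": (112, 129, 83, 57, 121),
    "neurosurgery": (94, 111, 81, 58, 81),
    "ent": (85, 82, 84, 57, 173),
    "orthopedics_1": (88, 67, 82, 72, 151),
    "orthopedics_2": (96, 73, 56, 54, 125),
    "urology": (105, 97, 117, 90, 134),
}

#: Yearly totals as published: 818, 858, 731, 553, 1025 (sum 3985).
YEARLY_COUNTS: dict[int, int] = {2019: 818, 2020: 858, 2021: 731, 2022: 553, 2023: 1025}

TOTAL_COLLECTED = 4018  #: questionnaires collected before quality control
TOTAL_RETAINED = 3985  #: questionnaires retained after quality control
OPERATED_TOTAL = 2994  #: respondents reporting surgery
Q2_ANSWERED = 2090  #: operated respondents answering the postoperative-care item
SURGERY_TOTAL_PCT = 75.13  #: published overall surgery percentage

#: Share of respondents who reported surgery, per ward and year.
SURGERY_RATES: dict[str, tuple[float, ...]] = {
    "plastic_surgery": (0.9911, 0.9930, 0.9684, 0.8824, 0.8846),
    "general_surgery_1": (0.6349, 0.6603, 0.6165, 0.8144, 0.8210),
    "general_surgery_2": (0.8036, 0.7597, 0.8313, 0.8772, 0.7851),
    "neurosurgery": (0.4574, 0.4775, 0.5432, 0.4655, 0.5309),
    "ent": (0.5294, 0.4024, 0.5714, 0.5088, 0.6127),
    "orthopedics_1": (0.9091, 0.8806, 0.8780, 0.9167, 0.9073),
    "orthopedics_2": (0.8125, 0.9041, 0.7679, 0.9444, 0.9280),
    "urology": (0.7238, 0.7629, 0.7692, 0.7667, 0.6940),
}

#: Ward-level mean respondent age in years (study-period column).
WARD_AGE_MEANS: dict[str, float] = {
    "plastic_surgery": 47.15,
    "general_surgery_1": 51.55,
    "general_surgery_2": 54.19,
    "neurosurgery": 54.14,
    "ent": 48.30,
    "orthopedics_1": 57.65,
    "orthopedics_2": 56.89,
    "urology": 55.88,
}

AGE_SD = 15.8  #: published age standard deviation, years
AGE_RANGE = (12.0, 96.0)  #: published respondent age range, years
AGE_MEAN_OVERALL = 53.03

MALE_PROB = 0.5315  #: published male share of questionnaires
#: urban / rural / not answered shares of the residence item
RESIDENCE_PROBS = {"urban": 0.4447, "rural": 0.3887, "missing": 0.1666}
#: education shares incl. the published "no answer" column
EDUCATION_PROBS = {
    "primary": 0.0520,
    "secondary": 0.1563,
    "high_school": 0.5220,
    "university": 0.2341,
    "missing": 0.0356,
}

#: Mean answer to the postoperative-care item (Q2), per ward and year.
LIKERT_Q2_MEANS: dict[str, tuple[float, ...]] = {
    "plastic_surgery": (4.93, 4.98, 4.99, 4.88, 4.97),
    "general_surgery_1": (4.23, 4.69, 4.78, 4.83, 4.80),
    "general_surgery_2": (4.93, 4.78, 4.82, 4.88, 4.99),
    "neurosurgery": (4.71, 4.83, 4.64, 4.82, 4.75),
    "ent": (4.71, 4.96, 5.00, 4.78, 4.96),
    "orthopedics_1": (4.70, 4.63, 4.84, 4.98, 4.79),
    "orthopedics_2": (4.63, 4.42, 4.82, 4.61, 4.35),
    "urology": (4.78, 4.80, 4.76, 4.71, 4.85),
}

#: Mean answer to the overall-impression item (Q3), per ward and year.
LIKERT_Q3_MEANS: dict[str, tuple[float, ...]] = {
    "plastic_surgery": (4.92, 4.88, 4.84, 4.88, 4.78),
    "general_surgery_1": (4.11, 4.69, 4.56, 4.60, 4.74),
    "general_surgery_2": (4.87, 4.73, 4.94, 4.85, 4.93),
    "neurosurgery": (4.59, 4.59, 4.39, 4.65, 4.70),
    "ent": (4.86, 4.74, 4.95, 4.70, 4.92),
    "orthopedics_1": (4.60, 4.39, 4.65, 4.79, 4.78),
    "orthopedics_2": (4.37, 4.15, 4.68, 4.54, 4.14),
    "urology": (4.62, 4.69, 4.65, 4.53, 4.79),
}

SPEARMAN_Q2_Q3 = 0.51  #: published rank correlation between Q2 and Q3

#: Yearly mean / SD of the algorithm total score, as published.
YEARLY_SCORE_MEANS: dict[int, float] = {2019: 2.09, 2020: 2.16, 2021: 1.70, 2022: 1.78, 2023: 1.50}
YEARLY_SCORE_SDS: dict[int, float] = {2019: 0.52, 2020: 0.55, 2021: 0.18, 2022: 0.42, 2023: 0.14}


@dataclass(frozen=True)
class PairedSummaryRow:
    """One published year-pair paired-test row (mean/SD of differences,
    95% CI bounds, t, two-sided p, significance flag)."""

    label: str
    year_a: int
    year_b: int
    mean_diff: float
    sd_diff: float
    ci95_low: float
    ci95_high: float
    t_stat: float
    p_two_sided: float
    significant: bool


#: All ten year-pair rows; the implied number of paired units is 6 (df = 5),
#: the only n jointly consistent with the printed t and CI columns.
PAIRED_SUMMARY_N = 6

PAIRED_SUMMARY_ROWS: tuple[PairedSummaryRow, ...] = (
    PairedSummaryRow("2019-2020", 2019, 2020, -0.06500, 0.61452, -0.70990, 0.57990, -0.259, 0.806, False),
    PairedSummaryRow("2019-2021", 2019, 2021, 0.39167, 0.62252, -0.26163, 1.04497, 1.541, 0.184, False),
    PairedSummaryRow("2019-2022", 2019, 2022, 0.30667, 0.62073, -0.34475, 0.95808, 1.210, 0.280, False),
    PairedSummaryRow("2019-2023", 2019, 2023, 0.58667, 0.38857, 0.17889, 0.99445, 3.698, 0.014, True),
    PairedSummaryRow("2020-2021", 2020, 2021, 0.45667, 0.49156, -0.05919, 0.97252, 2.276, 0.072, False),
    PairedSummaryRow("2020-2022", 2020, 2022, 0.37167, 0.66508, -0.32630, 1.06963, 1.369, 0.229, False),
    PairedSummaryRow("2020-2023", 2020, 2023, 0.65167, 0.51316, 0.11313, 1.19020, 3.111, 0.027, True),
    PairedSummaryRow("2021-2022", 2021, 2022, -0.08500, 0.52199, -0.63279, 0.46279, -0.399, 0.706, False),
    PairedSummaryRow("2021-2023", 2021, 2023, 0.19500, 0.26067, -0.07856, 0.46856, 1.832, 0.126, False),
    PairedSummaryRow("2022-2023", 2022, 2023, 0.28000, 0.45060, -0.19288, 0.75288, 1.522, 0.188, False),
)


def reference_consistency_checks() -> list[dict]:
    """Recompute every internally verifiable published number.

    Returns one row per check with the expected (printed) value, the value
    recomputed from the other printed numbers, and a pass flag:

    * each year-pair t statistic from its (mean difference, SD, n = 6);
    * the yearly questionnaire counts summing to the published total;
    * the overall surgery percentage from the operated / retained counts.
    """
    from .trend_stats import paired_t_from_summary

    rows: list[dict] = []
    for row in PAIRED_SUMMARY_ROWS:
        res = paired_t_from_summary(row.mean_diff, row.sd_diff, PAIRED_SUMMARY_N, label=row.label)
        rows.append(
            {
                "check": f"paired_t[{row.label}]",
                "expected": row.t_stat,
                "computed": round(res.t_stat, 3),
                "passed": round(res.t_stat, 3) == row.t_stat,
            }
        )
        rows.append(
            {
                "check": f"paired_p[{row.label}]",
                "expected": row.p_two_sided,
                "computed": round(res.p_two_sided, 3),
                "passed": round(res.p_two_sided, 3) == row.p_two_sided,
            }
        )
    total = sum(YEARLY_COUNTS.values())
    rows.append(
        {
            "check": "yearly_counts_total",
            "expected": TOTAL_RETAINED,
            "computed": total,
            "passed": total == TOTAL_RETAINED,
        }
    )
    ward_total = sum(sum(v) for v in WARD_YEAR_COUNTS.values())
    rows.append(
        {
            "check": "ward_year_counts_total",
            "expected": TOTAL_RETAINED,
            "computed": ward_total,
            "passed": ward_total == TOTAL_RETAINED,
        }
    )
    pct = round(100.0 * OPERATED_TOTAL / TOTAL_RETAINED, 2)
    rows.append(
        {
            "check": "surgery_total_pct",
            "expected": SURGERY_TOTAL_PCT,
            "computed": pct,
            "passed": pct == SURGERY_TOTAL_PCT,
        }
    )
    return rows
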