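"""Statistical pipeline for the five-year satisfaction trend analysis.

Covers the full inferential toolbox of the study design: ward/year Likert
summaries, one-way ANOVA with Tukey HSD post hoc, chi-square / Fisher exact
contingency tests, paired year-pair t-tests on aggregated algorithm scores,
a Shapiro-Wilk normality gate ahead of the Q2-Q3 correlation (Spearman when
normality is rejected, Pearson otherwise), Cronbach's alpha, and yearly
box-plot-style score summaries.

Standard tests are delegated to scipy; the paired t-test and Cronbach's
alpha are computed from their definitional formulas because the pipeline
must also reproduce printed summary rows from (mean, SD, n) alone.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateStatisticError
from .satisfaction_score import FactorWeights, score_dataset
from .survey_io import SurveyDataset

logger = logging.getLogger(__name__)

LIKERT_QUESTIONS = ("q2_postop_care", "q3_overall")

#: Default mapping of the eight wards onto six paired analysis units: the
#: two general-surgery wards and the two orthopedics wards are merged.
DEFAULT_WARD_CLUSTERS: dict[str, int] = {
    "plastic_surgery": 0,
    "general_surgery_1": 1,
    "general_surgery_2": 1,
    "neurosurgery": 2,
    "ent": 3,
    "orthopedics_1": 4,
    "orthopedics_2": 4,
    "urology": 5,
}


# ---------------------------------------------------------------------------
# result containers


@dataclass
class WardYearSummary:
    """Likert summary of one group cell (ward x year, year, or ward)."""

    ward: Optional[str]
    year: Optional[int]
    question: str
    n: int
    mean: float
    sd: float


@dataclass
class PairedTestResult:
    """One year-pair paired-samples test row."""

    label: str
    mean_diff: float
    sd_diff: float
    n_pairs: int
    t_stat: float
    df: int
    p_two_sided: float
    ci95_low: float
    ci95_high: float


@dataclass
class YearlyScoreSummary:
    """Box-plot summary of the algorithm total score for one year."""

    year: int
    n: int
    mean: float
    sd: Optional[float]
    median: float
    iqr_low: float
    iqr_high: float


# ---------------------------------------------------------------------------
# elementary operations


def likert_summary(
    dataset: SurveyDataset,
    question: str,
    grouping: Literal["ward_year", "year", "ward"] = "ward_year",
) -> list[WardYearSummary]:
    """Per-group n/mean/SD of a Likert item; missing answers dropped per cell,
    empty groups omitted."""
    if question not in LIKERT_QUESTIONS:
        raise ValueError(f"unknown Likert question: {question}")
    frame = dataset.frame
    keys = {"ward_year": ["ward", "year"], "year": ["year"], "ward": ["ward"]}[grouping]
    out: list[WardYearSummary] = []
    sub = frame.loc[frame[question].notna(), keys + [question]]
    for key, grp in sub.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(keys, key))
        vals = grp[question].astype(float)
        out.append(
            WardYearSummary(
                ward=info.get("ward"),
                year=int(info["year"]) if "year" in info else None,
                question=question,
                n=len(vals),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            )
        )
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float, int, int]:
    """Classical one-way ANOVA: returns (F, p, df_between, df_within).

    Raises :class:`DegenerateStatisticError` when the within-group mean
    square is zero (F undefined or infinite).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("at least two groups are required")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0.0:
        raise DegenerateStatisticError("zero within-group variance; F undefined")
    f_stat, p = sps.f_oneway(*arrs)
    return float(f_stat), float(p), k - 1, n_total - k


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD table: group indices, mean difference, adjusted p,
    and a reject flag at ``alpha``."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("at least two groups are required")
    res = sps.tukey_hsd(*arrs)
    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "mean_diff": float(arrs[i].mean() - arrs[j].mean()),
                "p_adj": p,
                "reject": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def contingency_test(
    table: Sequence[Sequence[int]],
    method: Literal["chi_square", "fisher", "auto"] = "auto",
    continuity_correction: bool = False,
) -> tuple[str, float, float]:
    """Chi-square or Fisher exact test of an r x c count table.

    Returns (method used, statistic, p).  The statistic is Pearson's
    chi-square, or the odds ratio for Fisher.  ``auto`` picks Fisher for a
    2x2 table with any expected count below 5, chi-square otherwise.  Tables
    with a zero margin are degenerate.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table must be a 2-D array of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateStatisticError("table has a zero margin")
    if method == "auto":
        if arr.shape == (2, 2):
            expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
            method = "fisher" if (expected < 5).any() else "chi_square"
        else:
            method = "chi_square"
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
        return "fisher", float(odds), float(p)
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    return "chi_square", float(chi2), float(p)


def paired_t(differences: Sequence[float], label: str = "") -> PairedTestResult:
    """Paired-samples t-test on within-pair differences.

    t = mean / (sd / sqrt(n)), df = n - 1, two-sided p, and the 95% CI
    mean +/- t_{0.975, df} * sd / sqrt(n).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("at least two paired differences are required")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStatisticError("zero variance of differences; t undefined")
    return paired_t_from_summary(float(d.mean()), sd, int(d.size), label=label)


def paired_t_from_summary(
    mean_diff: float, sd_diff: float, n_pairs: int, label: str = ""
) -> PairedTestResult:
    """Paired t-test from summary statistics (mean, SD, n of the differences).

    Identical formulas to :func:`paired_t`; lets printed summary rows be
    verified without the raw data.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be at least 2")
    if sd_diff <= 0:
        raise DegenerateStatisticError("sd_diff must be positive")
    df = n_pairs - 1
    se = sd_diff / np.sqrt(n_pairs)
    t_stat = mean_diff / se
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    half = float(sps.t.ppf(0.975, df)) * se
    return PairedTestResult(
        label=label,
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        n_pairs=int(n_pairs),
        t_stat=float(t_stat),
        df=df,
        p_two_sided=p,
        ci95_low=float(mean_diff - half),
        ci95_high=float(mean_diff + half),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test: returns (W, p).

    Used as the gate that selects a rank-based correlation when normality
    is rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(v) == 0.0:
        raise DegenerateStatisticError("constant sample; W undefined")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p from the large-sample
    t approximation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("at least 3 pairs are required")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise DegenerateStatisticError("constant input; rank variance is zero")
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), float(p)


def cronbach_alpha(items: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an n x k item matrix (rows with any missing value
    dropped; unbiased variance estimator).

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums)
    """
    mat = np.asarray(pd.DataFrame(items).dropna(), dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("at least two item columns are required")
    if mat.shape[0] < 2:
        raise ValueError("at least two complete respondents are required")
    k = mat.shape[1]
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise DegenerateStatisticError("zero total-score variance; alpha undefined")
    item_var = mat.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def yearly_score_summary(scores: pd.DataFrame) -> list[YearlyScoreSummary]:
    """Per-year mean/SD/median/IQR of algorithm totals.

    ``scores`` needs ``year`` and ``total_score`` columns.  The IQR uses
    linearly interpolated (type-7) percentiles; a single-score year reports
    its SD as missing.
    """
    out: list[YearlyScoreSummary] = []
    for year, grp in scores.groupby("year", sort=True):
        v = grp["total_score"].astype(float).to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out.append(
            YearlyScoreSummary(
                year=int(year),
                n=v.size,
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else None,
                median=float(med),
                iqr_low=float(q1),
                iqr_high=float(q3),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisConfig:
    """Settings of the end-to-end analysis."""

    group_count: int = 6  # paired units per year
    grouping: Literal["ward_cluster", "month_block"] = "ward_cluster"
    ward_clusters: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WARD_CLUSTERS))
    alpha: float = 0.05
    continuity_correction: bool = False
    multiple_correction: Optional[Literal["bonferroni", "holm"]] = None
    policy: Literal["strict", "neutral"] = "strict"


@dataclass
class AnalysisReport:
    """Every table the pipeline produces, plus skip reasons and settings."""

    yearly_counts: pd.DataFrame
    ward_year_counts: pd.DataFrame
    age_summary: pd.DataFrame
    age_anova: Optional[dict]
    surgery_rates: pd.DataFrame
    surgery_by_ward_test: Optional[dict]
    likert_means: pd.DataFrame
    likert_anova: pd.DataFrame
    scores: Optional[pd.DataFrame]
    score_report: Optional[dict]
    yearly_scores: pd.DataFrame
    paired_tests: pd.DataFrame
    normality: pd.DataFrame
    correlation: Optional[dict]
    cronbach: Optional[float]
    demographics: pd.DataFrame
    skipped: list[dict]
    settings: dict

    def save(self, outdir: str | Path) -> None:
        """Serialize as a directory of CSV tables plus summary.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.yearly_counts.to_csv(outdir / "counts.csv", index=False)
        self.ward_year_counts.to_csv(outdir / "ward_year_counts.csv", index=False)
        self.age_summary.round(2).to_csv(outdir / "ages.csv", index=False)
        self.surgery_rates.round(2).to_csv(outdir / "surgery_rates.csv", index=False)
        self.likert_means.round(2).to_csv(outdir / "likert_means.csv", index=False)
        if self.scores is not None:
            self.yearly_scores.round(3).to_csv(outdir / "scores_by_year.csv", index=False)
            self.paired_tests.round(3).to_csv(outdir / "paired_tests.csv", index=False)
        self.normality.round(4).to_csv(outdir / "normality.csv", index=False)
        corr = pd.DataFrame([self.correlation]) if self.correlation else pd.DataFrame()
        corr.to_csv(outdir / "correlation.csv", index=False)
        summary = {
            "settings": self.settings,
            "age_anova": self.age_anova,
            "surgery_by_ward_test": self.surgery_by_ward_test,
            "likert_anova": self.likert_anova.to_dict(orient="records"),
            "score_report": self.score_report,
            "yearly_scores": self.yearly_scores.to_dict(orient="records"),
            "paired_tests": self.paired_tests.to_dict(orient="records"),
            "normality": self.normality.to_dict(orient="records"),
            "correlation": self.correlation,
            "cronbach_alpha": self.cronbach,
            "demographics": self.demographics.to_dict(orient="records"),
            "skipped": self.skipped,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _adjust_pvalues(p: np.ndarray, method: Optional[str]) -> np.ndarray:
    if method is None:
        return p
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown correction: {method}")


def group_scores(
    scores: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Aggregate per-record scores into per-(year, group) means.

    The default ``ward_cluster`` grouping merges the eight wards into
    ``group_count`` clusters (pairing the two general-surgery and the two
    orthopedics wards); ``month_block`` is a positional round-robin split
    into ``group_count`` blocks within each year, for cohorts whose ward
    labels do not match the study's.
    """
    s = scores.copy()
    if config.grouping == "ward_cluster":
        clusters = {w: c % config.group_count for w, c in config.ward_clusters.items()}
        known = s["ward"].isin(clusters)
        if not known.all():
            extra = sorted(set(s.loc[~known, "ward"]))
            logger.warning("unmapped wards assigned round-robin: %s", extra)
            mapping = {w: i % config.group_count for i, w in enumerate(extra)}
            clusters = {**clusters, **mapping}
        s["group"] = s["ward"].map(clusters)
    else:
        s["group"] = s.groupby("year").cumcount() % config.group_count
    return (
        s.groupby(["year", "group"])["total_score"].mean().rename("group_mean").reset_index()
    )


def paired_year_tests(
    scores: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """All unordered year-pair paired t-tests on grouped score means.

    Differences are earlier-year minus later-year, so positive means mean a
    satisfaction improvement (scores fell).
    """
    grouped = group_scores(scores, config)
    years = sorted(grouped["year"].unique())
    wide = grouped.pivot(index="group", columns="year", values="group_mean")
    rows, skipped = [], []
    for ya, yb in itertools.combinations(years, 2):
        label = f"{ya}-{yb}"
        pair = wide[[ya, yb]].dropna()
        if len(pair) < 2:
            skipped.append({"analysis": f"paired_t[{label}]", "reason": "fewer than 2 complete pairs"})
            continue
        diffs = (pair[ya] - pair[yb]).to_numpy()
        try:
            res = paired_t(diffs, label=label)
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": f"paired_t[{label}]", "reason": str(exc)})
            continue
        rows.append(dataclasses.asdict(res))
    table = pd.DataFrame(rows)
    if len(table) and config.multiple_correction:
        table["p_adjusted"] = _adjust_pvalues(
            table["p_two_sided"].to_numpy(), config.multiple_correction
        )
    return table, skipped


def run_pipeline(
    dataset: SurveyDataset,
    weights: FactorWeights = FactorWeights(),
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the complete descriptive + inferential pipeline on a
    quality-filtered dataset and return every table as an
    :class:`AnalysisReport`.  Analyses that cannot run are skipped with a
    recorded reason, never fatally."""
    frame = dataset.frame
    skipped: list[dict] = []

    yearly_counts = (
        frame.groupby(frame["year"].astype(int)).size().rename("n").reset_index()
    )
    ward_year = (
        frame.groupby(["ward", frame["year"].astype(int)])
        .size()
        .rename("n")
        .reset_index()
        .pivot(index="ward", columns="year", values="n")
        .fillna(0)
        .astype(int)
        .reset_index()
    )

    # ward age profiles + across-ward ANOVA
    age_rows = []
    age_groups = []
    for ward, grp in frame.groupby("ward", sort=True):
        ages = grp["age"].dropna().astype(float)
        if len(ages):
            age_groups.append(ages.to_numpy())
            age_rows.append({"ward": ward, "n": len(ages), "mean_age": ages.mean(), "sd_age": ages.std(ddof=1)})
    age_summary = pd.DataFrame(age_rows)
    age_anova = None
    if len(age_groups) >= 2:
        try:
            f, p, dfb, dfw = anova_oneway(age_groups)
            age_anova = {"F": f, "p": p, "df_between": dfb, "df_within": dfw}
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": "age_anova", "reason": str(exc)})
    else:
        skipped.append({"analysis": "age_anova", "reason": "fewer than 2 wards with ages"})

    # surgery rates per ward x year + chi-square of surgery status by ward
    answered = frame.loc[frame["q1_surgery"].notna()]
    surgery_rates = (
        answered.assign(op=(answered["q1_surgery"] == "yes").astype(float))
        .groupby(["ward", answered["year"].astype(int)])["op"]
        .agg(rate="mean", n="size")
        .reset_index()
    )
    surgery_rates["pct"] = 100.0 * surgery_rates["rate"]
    surgery_by_ward_test = None
    counts = answered.groupby("ward")["q1_surgery"].value_counts().unstack(fill_value=0)
    if counts.shape[0] >= 2 and counts.shape[1] == 2 and (counts.sum(axis=1) > 0).all():
        try:
            meth, stat, p = contingency_test(
                counts.to_numpy(), method="chi_square",
                continuity_correction=config.continuity_correction,
            )
            surgery_by_ward_test = {"method": meth, "statistic": stat, "p": p}
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": "surgery_by_ward_test", "reason": str(exc)})
    else:
        skipped.append({"analysis": "surgery_by_ward_test", "reason": "degenerate surgery table"})

    # Likert summaries + per-ward across-year ANOVA per question
    likert_rows, anova_rows = [], []
    for question in LIKERT_QUESTIONS:
        cells = likert_summary(dataset, question, grouping="ward_year")
        likert_rows += [dataclasses.asdict(c) for c in cells]
        by_year = likert_summary(dataset, question, grouping="year")
        likert_rows += [dataclasses.asdict(c) | {"ward": "cumulative"} for c in by_year]
        for ward, grp in frame.groupby("ward", sort=True):
            groups = [
                g[question].dropna().astype(float).to_numpy()
                for _, g in grp.groupby(grp["year"].astype(int))
            ]
            groups = [g for g in groups if g.size]
            if len(groups) < 2 or sum(g.size for g in groups) <= len(groups):
                skipped.append(
                    {"analysis": f"likert_anova[{question},{ward}]", "reason": "insufficient data"}
                )
                continue
            try:
                f, p, dfb, dfw = anova_oneway(groups)
                anova_rows.append({"question": question, "ward": ward, "F": f, "p": p})
            except DegenerateStatisticError as exc:
                skipped.append({"analysis": f"likert_anova[{question},{ward}]", "reason": str(exc)})
        groups = [
            g[question].dropna().astype(float).to_numpy()
            for _, g in frame.groupby(frame["year"].astype(int))
        ]
        groups = [g for g in groups if g.size]
        if len(groups) >= 2:
            try:
                f, p, dfb, dfw = anova_oneway(groups)
                anova_rows.append({"question": question, "ward": "cumulative", "F": f, "p": p})
            except DegenerateStatisticError as exc:
                skipped.append({"analysis": f"likert_anova[{question},cumulative]", "reason": str(exc)})
    likert_means = pd.DataFrame(likert_rows)
    likert_anova = pd.DataFrame(anova_rows)

    # algorithm scoring + yearly summaries + paired year tests
    scores = score_rep = None
    yearly_scores = pd.DataFrame()
    paired = pd.DataFrame()
    if (frame["q1_surgery"] == "yes").any():
        scores, rep = score_dataset(dataset, weights, policy=config.policy)
        score_rep = dataclasses.asdict(rep)
        if len(scores):
            yearly_scores = pd.DataFrame(
                [dataclasses.asdict(s) for s in yearly_score_summary(scores)]
            )
            paired, pair_skips = paired_year_tests(scores, config)
            skipped += pair_skips
        else:
            skipped.append({"analysis": "scoring", "reason": "no scorable records"})
    else:
        skipped.append({"analysis": "scoring", "reason": "no operated respondents"})

    # normality gate, then Q2-Q3 correlation
    normality_rows = []
    correlation = None
    pair_frame = frame.loc[:, ["q2_postop_care", "q3_overall"]].dropna().astype(float)
    non_normal = False
    for question in LIKERT_QUESTIONS:
        vals = frame[question].dropna().astype(float).to_numpy()
        if vals.size < 3:
            skipped.append({"analysis": f"shapiro[{question}]", "reason": "fewer than 3 answers"})
            continue
        try:
            w, p = shapiro_wilk(vals)
            normality_rows.append({"question": question, "W": w, "p": p, "normal": p >= config.alpha})
            non_normal |= p < config.alpha
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": f"shapiro[{question}]", "reason": str(exc)})
            non_normal = True
    if len(pair_frame) >= 3:
        x = pair_frame["q2_postop_care"].to_numpy()
        y = pair_frame["q3_overall"].to_numpy()
        try:
            if non_normal or not normality_rows:
                rho, p = spearman_rho(x, y)
                correlation = {"method": "spearman", "rho": rho, "p": p, "n": len(pair_frame)}
            else:
                r, p = sps.pearsonr(x, y)
                correlation = {"method": "pearson", "rho": float(r), "p": float(p), "n": len(pair_frame)}
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": "correlation", "reason": str(exc)})
    else:
        skipped.append({"analysis": "correlation", "reason": "fewer than 3 complete Q2/Q3 pairs"})

    cronbach = None
    if len(pair_frame) >= 2:
        try:
            cronbach = cronbach_alpha(pair_frame)
        except DegenerateStatisticError as exc:
            skipped.append({"analysis": "cronbach_alpha", "reason": str(exc)})

    # sociodemographic comparisons of Q2
    demo_rows = []
    for factor in ("gender", "residence", "education"):
        sub = frame.loc[frame[factor].notna() & frame["q2_postop_care"].notna()]
        groups, levels = [], []
        for level, grp in sub.groupby(factor, sort=True):
            vals = grp["q2_postop_care"].astype(float).to_numpy()
            if vals.size:
                groups.append(vals)
                levels.append(level)
                demo_rows.append(
                    {"factor": factor, "level": level, "n": vals.size, "mean_q2": vals.mean()}
                )
        if len(groups) >= 2 and sum(g.size for g in groups) > len(groups):
            try:
                f, p, _, _ = anova_oneway(groups)
                demo_rows.append({"factor": factor, "level": "(anova)", "n": sum(g.size for g in groups), "mean_q2": np.nan, "F": f, "p": p})
            except DegenerateStatisticError as exc:
                skipped.append({"analysis": f"demographics[{factor}]", "reason": str(exc)})
        else:
            skipped.append({"analysis": f"demographics[{factor}]", "reason": "insufficient groups"})
    demographics = pd.DataFrame(demo_rows)

    for item in skipped:
        logger.info("skipped %s: %s", item["analysis"], item["reason"])

    return AnalysisReport(
        yearly_counts=yearly_counts,
        ward_year_counts=ward_year,
        age_summary=age_summary,
        age_anova=age_anova,
        surgery_rates=surgery_rates,
        surgery_by_ward_test=surgery_by_ward_test,
        likert_means=likert_means,
        likert_anova=likert_anova,
        scores=scores,
        score_report=score_rep,
        yearly_scores=yearly_scores,
        paired_tests=paired,
        normality=pd.DataFrame(normality_rows),
        correlation=correlation,
        cronbach=cronbach,
        demographics=demographics,
        skipped=skipped,
        settings=dataclasses.asdict(config),
    )
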