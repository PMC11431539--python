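"""Questionnaire I/O, schema validation, and quality-control filtering.

The canonical record is one respondent of a postoperative-satisfaction
questionnaire: calendar year and surgical ward (administrative), four
demographic items, the surgery indicator Q1, two 1-5 Likert items (Q2
postoperative care, Q3 overall impression), and the clinical inputs of the
satisfaction algorithm (infection, complication, protocol type, innovation
use, pain 0-10).

Quality control mirrors routine survey practice: questionnaires with more
than a configurable fraction (default 20%, strict inequality) of unanswered
in-scope items are discarded, and logically inconsistent questionnaires
(postoperative items answered by respondents who report no surgery) are
flagged.  Items that only apply to operated respondents do not count against
a non-operated respondent's missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: Canonical column order of the CSV interchange format.
COLUMNS: tuple[str, ...] = (
    "year",
    "ward",
    "age",
    "gender",
    "residence",
    "education",
    "q1_surgery",
    "q2_postop_care",
    "q3_overall",
    "infection",
    "complication",
    "protocol",
    "innovation",
    "pain",
)

MANDATORY_COLUMNS: tuple[str, ...] = ("year", "ward")

#: Admissible levels of each categorical item.
CATEGORICAL_LEVELS: dict[str, frozenset[str]] = {
    "gender": frozenset({"male", "female"}),
    "residence": frozenset({"urban", "rural"}),
    "education": frozenset({"primary", "secondary", "high_school", "university"}),
    "q1_surgery": frozenset({"yes", "no"}),
    "infection": frozenset({"yes", "no"}),
    "complication": frozenset({"yes", "no"}),
    "protocol": frozenset({"standard", "personalized"}),
    "innovation": frozenset({"yes", "no"}),
}

#: (low, high) inclusive ranges of the numeric items.
NUMERIC_RANGES: dict[str, tuple[float, float]] = {
    "age": (0.0, 120.0),
    "q2_postop_care": (1, 5),
    "q3_overall": (1, 5),
    "pain": (0, 10),
}

INTEGER_COLUMNS: tuple[str, ...] = ("year", "q2_postop_care", "q3_overall", "pain")

#: Items that only apply when the respondent reports surgery (Q1 = yes).
SURGERY_CONDITIONAL_FIELDS: frozenset[str] = frozenset(
    {"q2_postop_care", "infection", "complication", "protocol", "innovation", "pain"}
)

#: Default field set of the missingness rule: every item except the
#: administrative year/ward columns.
DEFAULT_QC_FIELDS: tuple[str, ...] = tuple(c for c in COLUMNS if c not in MANDATORY_COLUMNS)

#: Cell spellings accepted as "no answer" on read.
NA_TOKENS: tuple[str, ...] = ("", "na", "n/a", "no answer", "none")

#: Consistency-violation codes.
Q2_WITHOUT_SURGERY = "Q2_WITHOUT_SURGERY"
CLINICAL_WITHOUT_SURGERY = "CLINICAL_WITHOUT_SURGERY"


@dataclass
class QuestionnaireRecord:
    """One respondent's answers; ``None`` encodes a missing answer."""

    year: Optional[int] = None
    ward: Optional[str] = None
    age: Optional[float] = None
    gender: Optional[str] = None
    residence: Optional[str] = None
    education: Optional[str] = None
    q1_surgery: Optional[str] = None
    q2_postop_care: Optional[int] = None
    q3_overall: Optional[int] = None
    infection: Optional[str] = None
    complication: Optional[str] = None
    protocol: Optional[str] = None
    innovation: Optional[str] = None
    pain: Optional[int] = None


@dataclass
class ExclusionReport:
    """Summary of a quality-control partition."""

    n_input: int
    n_retained: int
    n_excluded: int
    threshold: float
    fields_in_scope: tuple[str, ...]
    reasons: dict[str, int] = field(default_factory=dict)


class SurveyDataset:
    """An ordered collection of questionnaire records.

    Internally a :class:`pandas.DataFrame` in the canonical schema; rows keep
    their positional identity (``record_id``) across partitions so that
    retained + excluded always reconstructs the input.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
        self.frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[QuestionnaireRecord]:
        return iter(self.records())

    def records(self) -> list[QuestionnaireRecord]:
        """Materialize rows as :class:`QuestionnaireRecord` objects."""
        out = []
        for row in self.frame.itertuples(index=False):
            d = dict(zip(COLUMNS, row))
            for k, v in d.items():
                if pd.isna(v):
                    d[k] = None
                elif k in INTEGER_COLUMNS:
                    d[k] = int(v)
            out.append(QuestionnaireRecord(**d))
        return out

    @classmethod
    def from_records(
        cls, records: Sequence[QuestionnaireRecord], provenance: str = ""
    ) -> "SurveyDataset":
        rows = [{f.name: getattr(r, f.name) for f in dc_fields(QuestionnaireRecord)} for r in records]
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(_normalize_dtypes(frame), provenance)

    def equals(self, other: "SurveyDataset") -> bool:
        """Field-for-field equality, treating missing values as equal."""
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        for col in COLUMNS:
            xa, xb = a[col], b[col]
            na = xa.isna()
            if not na.equals(xb.isna()):
                return False
            if col == "age":
                if not np.allclose(xa[~na].astype(float), xb[~na].astype(float), atol=1e-9):
                    return False
            elif not (xa[~na].astype(object) == xb[~na].astype(object)).all():
                return False
        return True


def _normalize_dtypes(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for col in INTEGER_COLUMNS:
        frame[col] = pd.array(
            [None if pd.isna(v) else int(v) for v in frame[col]], dtype="Int64"
        )
    frame["age"] = pd.to_numeric(frame["age"], errors="coerce").astype(float)
    for col in CATEGORICAL_LEVELS:
        frame[col] = frame[col].astype(object).where(frame[col].notna(), np.nan)
    frame["ward"] = frame["ward"].astype(object)
    return frame


def read_survey(
    path: str | Path,
    delimiter: str = ",",
    column_map: Optional[dict[str, str]] = None,
) -> SurveyDataset:
    """Read a questionnaire CSV into a :class:`SurveyDataset`.

    Header names are matched case-insensitively against the canonical schema
    (``column_map`` adds extra alias -> canonical entries).  Unparseable or
    out-of-range cells become missing values; each coercion is counted and
    logged, never fatal.  Missing ``year``/``ward`` columns raise
    :class:`~postopsat.errors.SchemaError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} has no header row") from exc
    alias = {c.lower(): c for c in COLUMNS}
    if column_map:
        alias.update({k.lower(): v for k, v in column_map.items()})
    rename = {}
    for col in raw.columns:
        canon = alias.get(col.strip().lower())
        if canon:
            rename[col] = canon
    raw = raw.rename(columns=rename)
    absent = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if absent:
        raise SchemaError(f"missing mandatory columns: {', '.join(absent)}")
    for col in COLUMNS:
        if col not in raw.columns:
            raw[col] = ""

    n_warn = 0
    frame = pd.DataFrame(index=raw.index)
    for col in COLUMNS:
        cells = raw[col].astype(str).str.strip()
        is_na = cells.str.lower().isin(NA_TOKENS)
        if col in CATEGORICAL_LEVELS or col == "ward":
            vals = cells.str.lower().str.replace(" ", "_", regex=False)
            if col in CATEGORICAL_LEVELS:
                bad = ~is_na & ~vals.isin(CATEGORICAL_LEVELS[col])
                if bad.any():
                    n_warn += int(bad.sum())
                    logger.warning(
                        "%s: %d unrecognized %r values set to missing", path.name, bad.sum(), col
                    )
                vals = vals.where(~bad)
            frame[col] = vals.where(~is_na)
        else:
            num = pd.to_numeric(cells.where(~is_na), errors="coerce")
            bad = num.isna() & ~is_na
            lo, hi = NUMERIC_RANGES.get(col, (-np.inf, np.inf))
            out = num.notna() & ((num < lo) | (num > hi))
            if col in INTEGER_COLUMNS:
                frac = num.notna() & (num != num.round())
                out |= frac
            if col == "year":
                out = pd.Series(False, index=num.index)
            if (bad | out).any():
                n_warn += int((bad | out).sum())
                logger.warning(
                    "%s: %d unparseable/out-of-range %r values set to missing",
                    path.name,
                    (bad | out).sum(),
                    col,
                )
            frame[col] = num.where(~out)
    ds = SurveyDataset(_normalize_dtypes(frame), provenance=str(path))
    ds.parse_warnings = n_warn  # type: ignore[attr-defined]
    return ds


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a dataset to CSV; missing answers become empty cells.

    Round-trips through :func:`read_survey` field-for-field.
    """
    frame = dataset.frame.copy()
    frame["age"] = frame["age"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    frame.to_csv(path, index=False, na_rep="")


def missingness_fraction(
    record: QuestionnaireRecord, fields_in_scope: Sequence[str]
) -> float:
    """Fraction of the given fields that are unanswered on this record."""
    if not fields_in_scope:
        raise ValueError("fields_in_scope must be non-empty")
    n_missing = sum(1 for f in fields_in_scope if getattr(record, f) is None)
    return n_missing / len(fields_in_scope)


def applicable_fields(
    record: QuestionnaireRecord, fields_in_scope: Sequence[str]
) -> tuple[str, ...]:
    """Fields of ``fields_in_scope`` that apply to this respondent.

    Surgery-conditional items (Q2 and the clinical algorithm inputs) are
    dropped when the respondent explicitly reports no surgery; they stay in
    scope when Q1 is "yes" or itself unanswered.
    """
    if record.q1_surgery == "no":
        return tuple(f for f in fields_in_scope if f not in SURGERY_CONDITIONAL_FIELDS)
    return tuple(fields_in_scope)


def apply_exclusion(
    dataset: SurveyDataset,
    threshold: float = 0.20,
    fields_in_scope: Sequence[str] = DEFAULT_QC_FIELDS,
    skip_inapplicable: bool = True,
) -> tuple[SurveyDataset, SurveyDataset, ExclusionReport]:
    """Partition a dataset by the missingness rule.

    A record is excluded iff its missingness fraction strictly exceeds
    ``threshold`` ("over 20%" with the default).  With ``skip_inapplicable``
    (default), surgery-conditional items are not counted against respondents
    who report no surgery; set it to ``False`` for the literal
    all-fields-in-scope rule.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if not fields_in_scope:
        raise ValueError("fields_in_scope must be non-empty")
    frame = dataset.frame
    miss = frame.loc[:, list(fields_in_scope)].isna()
    n_scope = pd.Series(len(fields_in_scope), index=frame.index, dtype=float)
    n_missing = miss.sum(axis=1).astype(float)
    if skip_inapplicable:
        cond = [f for f in fields_in_scope if f in SURGERY_CONDITIONAL_FIELDS]
        if cond:
            not_operated = frame["q1_surgery"] == "no"
            n_scope = n_scope - not_operated * len(cond)
            n_missing = n_missing - miss.loc[:, cond].sum(axis=1) * not_operated
    frac = n_missing / n_scope
    excl_mask = (frac > threshold).to_numpy()
    retained = SurveyDataset(frame.loc[~excl_mask], provenance=dataset.provenance)
    excluded = SurveyDataset(frame.loc[excl_mask], provenance=dataset.provenance)
    report = ExclusionReport(
        n_input=len(frame),
        n_retained=len(retained),
        n_excluded=len(excluded),
        threshold=threshold,
        fields_in_scope=tuple(fields_in_scope),
        reasons={"missingness_over_threshold": int(excl_mask.sum())},
    )
    logger.info(
        "exclusion: %d in, %d retained, %d excluded (threshold %.2f)",
        report.n_input,
        report.n_retained,
        report.n_excluded,
        threshold,
    )
    return retained, excluded, report


def consistency_check(record: QuestionnaireRecord) -> list[str]:
    """Logical-consistency codes for one record (empty list = consistent).

    Rules: (a) Q2 answered although the respondent reports no surgery;
    (b) any clinical algorithm input answered although Q1 = no.
    """
    codes: list[str] = []
    if record.q1_surgery == "no":
        if record.q2_postop_care is not None:
            codes.append(Q2_WITHOUT_SURGERY)
        clinical = ("infection", "complication", "protocol", "innovation", "pain")
        if any(getattr(record, f) is not None for f in clinical):
            codes.append(CLINICAL_WITHOUT_SURGERY)
    return codes


def apply_consistency_filter(
    dataset: SurveyDataset,
) -> tuple[SurveyDataset, SurveyDataset, dict[str, int]]:
    """Partition into consistent and flagged records, with per-code counts."""
    frame = dataset.frame
    not_op = frame["q1_surgery"] == "no"
    q2_bad = not_op & frame["q2_postop_care"].notna()
    clinical = ["infection", "complication", "protocol", "innovation", "pain"]
    clin_bad = not_op & frame.loc[:, clinical].notna().any(axis=1)
    flagged = (q2_bad | clin_bad).to_numpy()
    counts = {
        Q2_WITHOUT_SURGERY: int(q2_bad.sum()),
        CLINICAL_WITHOUT_SURGERY: int(clin_bad.sum()),
    }
    return (
        SurveyDataset(frame.loc[~flagged], provenance=dataset.provenance),
        SurveyDataset(frame.loc[flagged], provenance=dataset.provenance),
        counts,
    )
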