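"""Core data types, cohort CSV/JSON I/O, unit conversions and inclusion filters.

The clustering operates on five routine clinical variables measured close to
diagnosis of type 2 diabetes:

* age at first visit (years)
* BMI (kg/m^2)
* HbA1c (mmol/mol, IFCC scale)
* C-peptide (nmol/l)
* HDL-cholesterol (mmol/l)

HbA1c is stored internally on the IFCC scale only; the NGSP percent scale is
a display/IO conversion via the IFCC-NGSP master equation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ARCHETYPES",
    "CLUSTERING_VARIABLES",
    "COHORT_CSV_COLUMNS",
    "Cohort",
    "InclusionReport",
    "RowParseError",
    "SchemaError",
    "SubjectRecord",
    "apply_inclusion_criteria",
    "hba1c_ifcc_to_ngsp",
    "hba1c_ngsp_to_ifcc",
    "read_cohort",
    "write_cohort",
]

#: canonical order of the five clustering variables
CLUSTERING_VARIABLES = ("age_at_first_visit", "bmi", "hba1c", "c_peptide", "hdl")

#: the five archetypes of the five-cluster solution, in canonical order:
#: severe insulin-deficient (SIDD), severe insulin-resistant (SIRD),
#: mild obesity-related (MOD), mild (MD), mild with high HDL (MDH)
ARCHETYPES = ("SIDD", "SIRD", "MOD", "MD", "MDH")

#: documented cohort CSV header
COHORT_CSV_COLUMNS = (
    "subject_id",
    "cohort_id",
    "sex",
    "age_at_diagnosis",
    "age_at_first_visit",
    "bmi",
    "hba1c_mmol_mol",
    "c_peptide_nmol_l",
    "hdl_mmol_l",
    "gad_positive",
    "diagnosis_date",
    "first_visit_date",
)

# duration constants (days); calendar durations are fixed-length by convention
DAYS_PER_YEAR = 365.25
TWO_YEARS_DAYS = 730
THREE_MONTHS_DAYS = 90
SIX_MONTHS_DAYS = 183

# IFCC (mmol/mol) <-> NGSP (%) master equation coefficients
_NGSP_SLOPE = 0.09148
_NGSP_INTERCEPT = 2.152

SEXES = ("male", "female")


class SchemaError(ValueError):
    """A mandatory column is missing or malformed in an input table."""


class RowParseError(ValueError):
    """A row-level value could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass
class SubjectRecord:
    """One individual's clustering variables plus inclusion fields.

    Numeric fields are ``None`` when absent (never zero). HbA1c is on the
    IFCC mmol/mol scale.
    """

    subject_id: str
    cohort_id: str
    sex: str
    age_at_diagnosis: float | None = None
    age_at_first_visit: float | None = None
    bmi: float | None = None
    hba1c: float | None = None
    c_peptide: float | None = None
    hdl: float | None = None
    gad_positive: bool | None = None
    diagnosis_date: datetime.date | None = None
    first_visit_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    def clustering_values(self) -> tuple[float | None, ...]:
        """The five clustering variables in canonical order."""
        return (self.age_at_first_visit, self.bmi, self.hba1c,
                self.c_peptide, self.hdl)

    @property
    def has_complete_clustering_variables(self) -> bool:
        return all(v is not None for v in self.clustering_values())


@dataclass
class Cohort:
    """An ordered collection of subjects sharing a cohort identifier."""

    cohort_id: str
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate subject_id in cohort {self.cohort_id}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subset(self, subjects: Iterable[SubjectRecord]) -> "Cohort":
        return Cohort(self.cohort_id, list(subjects))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view using the documented CSV column names."""
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "cohort_id": s.cohort_id,
                "sex": s.sex,
                "age_at_diagnosis": s.age_at_diagnosis,
                "age_at_first_visit": s.age_at_first_visit,
                "bmi": s.bmi,
                "hba1c_mmol_mol": s.hba1c,
                "c_peptide_nmol_l": s.c_peptide,
                "hdl_mmol_l": s.hdl,
                "gad_positive": s.gad_positive,
                "diagnosis_date": s.diagnosis_date.isoformat() if s.diagnosis_date else None,
                "first_visit_date": s.first_visit_date.isoformat() if s.first_visit_date else None,
            })
        return pd.DataFrame(rows, columns=list(COHORT_CSV_COLUMNS))


@dataclass
class InclusionReport:
    """Bookkeeping for inclusion filtering with first-failing-rule attribution."""

    n_input: int
    n_retained: int
    n_excluded_by_rule: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.n_excluded_by_rule.values()):
            raise ValueError("exclusion counts do not add up to n_input")

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def hba1c_ifcc_to_ngsp(ifcc: float) -> float:
    """Convert HbA1c from IFCC mmol/mol to NGSP percent.

    Uses the IFCC-NGSP master equation ``NGSP% = 0.09148 * IFCC + 2.152``;
    e.g. 49.7 mmol/mol -> 6.7% and the 69 mmol/mol insulin-requirement
    threshold -> 8.5%.
    """
    if ifcc <= 0:
        raise ValueError(f"IFCC HbA1c must be positive, got {ifcc}")
    return _NGSP_SLOPE * ifcc + _NGSP_INTERCEPT


def hba1c_ngsp_to_ifcc(ngsp: float) -> float:
    """Inverse of :func:`hba1c_ifcc_to_ngsp` (exact to floating point)."""
    ifcc = (ngsp - _NGSP_INTERCEPT) / _NGSP_SLOPE
    if ifcc <= 0:
        raise ValueError(f"NGSP value {ngsp} maps to non-positive IFCC value")
    return ifcc


def _parse_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise RowParseError(row, f"cannot parse {column}={text!r} as number") from exc


def _parse_bool(value, row: int, column: str) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise RowParseError(row, f"cannot parse {column}={value!r} as boolean")


def _parse_date(value, row: int, column: str) -> datetime.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return datetime.date.fromisoformat(text)
    except ValueError as exc:
        raise RowParseError(row, f"cannot parse {column}={text!r} as ISO date") from exc


def read_cohort(path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort table from CSV.

    Parameters
    ----------
    path
        CSV file with the documented header (`COHORT_CSV_COLUMNS`).
    schema
        Optional map from canonical column name to the actual column name in
        the file, for cohorts exported under local naming conventions.

    Missing numeric cells become ``None`` on the record, never zero.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in COHORT_CSV_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [canon for canon, actual in colmap.items() if actual not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(sorted(missing))}")

    subjects: list[SubjectRecord] = []
    cohort_ids: set[str] = set()
    for row, rec in enumerate(frame.to_dict("records")):
        get = lambda canon: rec[colmap[canon]]  # noqa: E731
        sex = str(get("sex")).strip().lower()
        if sex not in SEXES:
            raise RowParseError(row, f"sex must be one of {SEXES}, got {get('sex')!r}")
        subjects.append(SubjectRecord(
            subject_id=str(get("subject_id")).strip(),
            cohort_id=str(get("cohort_id")).strip(),
            sex=sex,
            age_at_diagnosis=_parse_float(get("age_at_diagnosis"), row, "age_at_diagnosis"),
            age_at_first_visit=_parse_float(get("age_at_first_visit"), row, "age_at_first_visit"),
            bmi=_parse_float(get("bmi"), row, "bmi"),
            hba1c=_parse_float(get("hba1c_mmol_mol"), row, "hba1c_mmol_mol"),
            c_peptide=_parse_float(get("c_peptide_nmol_l"), row, "c_peptide_nmol_l"),
            hdl=_parse_float(get("hdl_mmol_l"), row, "hdl_mmol_l"),
            gad_positive=_parse_bool(get("gad_positive"), row, "gad_positive"),
            diagnosis_date=_parse_date(get("diagnosis_date"), row, "diagnosis_date"),
            first_visit_date=_parse_date(get("first_visit_date"), row, "first_visit_date"),
        ))
        cohort_ids.add(subjects[-1].cohort_id)
    if len(cohort_ids) > 1:
        raise SchemaError(f"file mixes cohort_ids {sorted(cohort_ids)}")
    cohort_id = cohort_ids.pop() if cohort_ids else ""
    return Cohort(cohort_id, subjects)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV with the documented header (round-trip safe)."""
    frame = cohort.to_frame()
    # blank cells for absent values, matching what read_cohort parses back
    frame.to_csv(path, index=False, na_rep="")


# ordered inclusion rules; each excluded subject is attributed to the FIRST
# failing rule so reports are deterministic
_INCLUSION_RULE_ORDER = ("age", "window", "gad", "completeness")


def apply_inclusion_criteria(
    cohort: Cohort,
    gad_policy: str = "exclude_only_positive",
    min_age_at_diagnosis: float = 35.0,
    max_window_days: int = TWO_YEARS_DAYS,
) -> tuple[Cohort, InclusionReport]:
    """Apply the study inclusion criteria and report exclusions.

    Retained subjects have age at diagnosis >= 35 years, a first visit within
    two years (730 days) of diagnosis, are not GAD-positive, and have all five
    clustering variables present. A rule also fails when the fields it needs
    are missing (e.g. an absent diagnosis date fails the window rule).

    ``gad_policy`` is either ``"exclude_only_positive"`` (default: subjects
    with unmeasured GAD status are kept) or ``"require_negative"`` (subjects
    with unmeasured GAD status are excluded), reflecting differing antibody
    measurement coverage between real-world cohorts.
    """
    if gad_policy not in ("exclude_only_positive", "require_negative"):
        raise ValueError(f"unknown gad_policy {gad_policy!r}")

    def failing_rule(s: SubjectRecord) -> str | None:
        if s.age_at_diagnosis is None or s.age_at_diagnosis < min_age_at_diagnosis:
            return "age"
        if s.diagnosis_date is None or s.first_visit_date is None:
            return "window"
        delta = (s.first_visit_date - s.diagnosis_date).days
        if delta < 0 or delta > max_window_days:
            return "window"
        if s.gad_positive is True:
            return "gad"
        if s.gad_positive is None and gad_policy == "require_negative":
            return "gad"
        if not s.has_complete_clustering_variables:
            return "completeness"
        return None

    retained: list[SubjectRecord] = []
    excluded = {rule: 0 for rule in _INCLUSION_RULE_ORDER}
    for s in cohort:
        rule = failing_rule(s)
        if rule is None:
            retained.append(s)
        else:
            excluded[rule] += 1
    report = InclusionReport(
        n_input=len(cohort),
        n_retained=len(retained),
        n_excluded_by_rule={r: c for r, c in excluded.items()},
    )
    return cohort.subset(retained), report
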