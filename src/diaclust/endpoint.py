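"""Composite time-to-insulin-requirement endpoint.

The event is the earlier of two pathways:

* *sustained insulin*: start of an insulin treatment episode lasting more
  than six months (183 days), where prescription intervals separated by at
  most ``max_gap`` days are merged into episodes; or
* *glycaemic requirement*: two HbA1c measurements strictly above
  69 mmol/mol (8.5%) at least three months (90 days) apart, with at least
  two distinct non-insulin glucose-lowering drug classes active at both
  measurement dates.

Subjects with neither pathway are censored at their last observation date.
Time zero defaults to the diagnosis date.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import pandas as pd

from .data_model import SIX_MONTHS_DAYS, THREE_MONTHS_DAYS

__all__ = [
    "EndpointConfig",
    "EndpointResult",
    "Episode",
    "Hba1cMeasurement",
    "LongitudinalRecord",
    "PrescriptionInterval",
    "detect_glycaemic_requirement",
    "detect_sustained_insulin",
    "endpoint_table",
    "longitudinal_from_frames",
    "longitudinal_to_frames",
    "time_to_insulin_requirement",
    "treatment_episodes",
]


@dataclass(frozen=True)
class PrescriptionInterval:
    """One prescription of a glucose-lowering drug class.

    ``end_date=None`` marks an open (ongoing) interval.
    """

    subject_id: str
    drug_class: str
    is_insulin: bool
    start_date: datetime.date
    end_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.end_date is not None and self.end_date < self.start_date:
            raise ValueError(
                f"{self.subject_id}/{self.drug_class}: end_date before start_date")


@dataclass(frozen=True)
class Hba1cMeasurement:
    subject_id: str
    date: datetime.date
    value: float  # mmol/mol

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("HbA1c must be positive")


@dataclass(frozen=True)
class Episode:
    """A merged treatment episode for one drug class."""

    drug_class: str
    is_insulin: bool
    start: datetime.date
    end: datetime.date | None  # None = ongoing

    def duration_days(self) -> float:
        if self.end is None:
            return float("inf")
        return (self.end - self.start).days

    def active_on(self, date: datetime.date) -> bool:
        if date < self.start:
            return False
        return self.end is None or date <= self.end


@dataclass
class LongitudinalRecord:
    """All endpoint inputs for one individual."""

    subject_id: str
    time_zero: datetime.date
    censor_date: datetime.date
    prescriptions: list[PrescriptionInterval] = field(default_factory=list)
    hba1c: list[Hba1cMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.censor_date < self.time_zero:
            raise ValueError(f"{self.subject_id}: censor date before time zero")
        self.hba1c = sorted(self.hba1c, key=lambda m: m.date)


@dataclass(frozen=True)
class EndpointResult:
    subject_id: str
    time_days: int
    event: bool
    pathway: str  # sustained_insulin | glycaemic_requirement | censored

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("negative follow-up time")
        if (self.pathway == "censored") == self.event:
            raise ValueError("pathway 'censored' iff event is False")


@dataclass(frozen=True)
class EndpointConfig:
    """Constants of the composite endpoint definition (days, mmol/mol)."""

    hba1c_threshold: float = 69.0          # strict '>' per definition
    min_separation_days: int = THREE_MONTHS_DAYS   # '>= 3 months'
    min_oral_classes: int = 2
    sustained_min_days: int = SIX_MONTHS_DAYS      # '> 6 months'
    max_gap_days: int = 90                 # prescription-merging gap


def treatment_episodes(
    prescriptions: list[PrescriptionInterval], max_gap: int = 90,
) -> dict[str, list[Episode]]:
    """Merge date-sorted prescription intervals into episodes per drug class.

    Intervals of the same class whose gap is at most ``max_gap`` days are
    merged. An open interval absorbs every later interval of its class.
    """
    by_class: dict[str, list[PrescriptionInterval]] = {}
    for p in prescriptions:
        by_class.setdefault(p.drug_class, []).append(p)

    episodes: dict[str, list[Episode]] = {}
    for drug_class, items in by_class.items():
        items = sorted(items, key=lambda p: (p.start_date, p.end_date or datetime.date.max))
        merged: list[Episode] = []
        cur_start, cur_end = items[0].start_date, items[0].end_date
        is_insulin = items[0].is_insulin
        for p in items[1:]:
            if cur_end is None or (p.start_date - cur_end).days <= max_gap:
                if cur_end is not None:
                    if p.end_date is None:
                        cur_end = None
                    else:
                        cur_end = max(cur_end, p.end_date)
            else:
                merged.append(Episode(drug_class, is_insulin, cur_start, cur_end))
                cur_start, cur_end = p.start_date, p.end_date
        merged.append(Episode(drug_class, is_insulin, cur_start, cur_end))
        episodes[drug_class] = merged
    return episodes


def detect_sustained_insulin(
    record: LongitudinalRecord,
    max_gap: int = 90,
    min_duration: int = SIX_MONTHS_DAYS,
) -> datetime.date | None:
    """Date of the earliest insulin episode lasting more than ``min_duration``.

    Returns the episode *start* date, or None when no episode qualifies.
    """
    episodes = treatment_episodes(
        [p for p in record.prescriptions if p.is_insulin], max_gap=max_gap)
    candidates = [
        e.start
        for eps in episodes.values()
        for e in eps
        if e.duration_days() > min_duration
    ]
    return min(candidates) if candidates else None


def detect_glycaemic_requirement(
    record: LongitudinalRecord,
    threshold: float = 69.0,
    min_separation: int = THREE_MONTHS_DAYS,
    min_oral_classes: int = 2,
    max_gap: int = 90,
) -> datetime.date | None:
    """Date at which insulin requirement is established glycaemically.

    Finds the earliest measurement pair (t1 < t2) with both HbA1c values
    strictly above ``threshold``, t2 - t1 >= ``min_separation`` days, and at
    least ``min_oral_classes`` distinct non-insulin drug classes active at
    both dates. The event date is t2 (the requirement is established at the
    second measurement).
    """
    episodes = treatment_episodes(
        [p for p in record.prescriptions if not p.is_insulin], max_gap=max_gap)

    def n_active_classes(date: datetime.date) -> int:
        return sum(
            any(e.active_on(date) for e in eps) for eps in episodes.values())

    qualifying = [
        m.date
        for m in record.hba1c
        if m.value > threshold and n_active_classes(m.date) >= min_oral_classes
    ]
    if len(qualifying) < 2:
        return None
    earliest = qualifying[0]
    for t2 in qualifying[1:]:
        if (t2 - earliest).days >= min_separation:
            return t2
    return None


def time_to_insulin_requirement(
    record: LongitudinalRecord, config: EndpointConfig | None = None,
) -> EndpointResult:
    """Derive the composite endpoint for one individual.

    The event date is the earlier of the two pathway dates; on an exact tie
    the sustained-insulin pathway is recorded. If neither pathway fires the
    subject is censored at the last observation date.
    """
    config = config or EndpointConfig()
    insulin_date = detect_sustained_insulin(
        record, max_gap=config.max_gap_days,
        min_duration=config.sustained_min_days)
    glycaemic_date = detect_glycaemic_requirement(
        record, threshold=config.hba1c_threshold,
        min_separation=config.min_separation_days,
        min_oral_classes=config.min_oral_classes,
        max_gap=config.max_gap_days)

    candidates: list[tuple[datetime.date, str]] = []
    if insulin_date is not None:
        candidates.append((insulin_date, "sustained_insulin"))
    if glycaemic_date is not None:
        candidates.append((glycaemic_date, "glycaemic_requirement"))
    if not candidates:
        return EndpointResult(
            record.subject_id,
            (record.censor_date - record.time_zero).days, False, "censored")
    # tie-break: sustained_insulin sorts first by insertion order via min on date only
    event_date, pathway = min(candidates, key=lambda c: c[0])
    if event_date < record.time_zero:
        raise ValueError(
            f"{record.subject_id}: event {event_date} before time zero {record.time_zero}")
    return EndpointResult(
        record.subject_id, (event_date - record.time_zero).days, True, pathway)


def longitudinal_to_frames(
    records: list[LongitudinalRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten records into (subjects, prescriptions, hba1c) tables.

    The subjects table carries time_zero and censor_date; the prescription
    table has columns subject_id, drug_class, is_insulin, start_date,
    end_date (blank = open); the HbA1c table subject_id, date,
    value_mmol_mol. All dates ISO-8601.
    """
    subjects = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "time_zero": [r.time_zero.isoformat() for r in records],
        "censor_date": [r.censor_date.isoformat() for r in records],
    })
    rx = pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "drug_class": p.drug_class,
                "is_insulin": p.is_insulin,
                "start_date": p.start_date.isoformat(),
                "end_date": p.end_date.isoformat() if p.end_date else "",
            }
            for r in records
            for p in r.prescriptions
        ],
        columns=["subject_id", "drug_class", "is_insulin", "start_date", "end_date"],
    )
    hba1c = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "date": m.date.isoformat(),
                "value_mmol_mol": m.value,
            }
            for r in records
            for m in r.hba1c
        ],
        columns=["subject_id", "date", "value_mmol_mol"],
    )
    return subjects, rx, hba1c


def longitudinal_from_frames(
    subjects: pd.DataFrame, rx: pd.DataFrame, hba1c: pd.DataFrame,
) -> list[LongitudinalRecord]:
    """Inverse of :func:`longitudinal_to_frames`."""
    date = datetime.date.fromisoformat
    rx_by: dict[str, list[PrescriptionInterval]] = {}
    for row in rx.itertuples():
        end = str(row.end_date).strip()
        rx_by.setdefault(str(row.subject_id), []).append(PrescriptionInterval(
            subject_id=str(row.subject_id),
            drug_class=str(row.drug_class),
            is_insulin=str(row.is_insulin).lower() in ("true", "1"),
            start_date=date(str(row.start_date)),
            end_date=date(end) if end and end.lower() != "nan" else None,
        ))
    meas_by: dict[str, list[Hba1cMeasurement]] = {}
    for row in hba1c.itertuples():
        meas_by.setdefault(str(row.subject_id), []).append(Hba1cMeasurement(
            subject_id=str(row.subject_id),
            date=date(str(row.date)),
            value=float(row.value_mmol_mol),
        ))
    records = []
    for row in subjects.itertuples():
        sid = str(row.subject_id)
        records.append(LongitudinalRecord(
            subject_id=sid,
            time_zero=date(str(row.time_zero)),
            censor_date=date(str(row.censor_date)),
            prescriptions=rx_by.get(sid, []),
            hba1c=meas_by.get(sid, []),
        ))
    return records


def endpoint_table(
    records: list[LongitudinalRecord], config: EndpointConfig | None = None,
) -> pd.DataFrame:
    """EndpointResult rows for a collection of subjects, as a DataFrame."""
    results = [time_to_insulin_requirement(r, config) for r in records]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "time_days": [r.time_days for r in results],
            "event": [r.event for r in results],
            "pathway": [r.pathway for r in results],
        }
    )
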