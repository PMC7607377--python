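"""Patient records, cohort tables, and pre-fit exclusion rules.

Before any model is fitted, records with incomplete required fields or values
outside accepted clinical ranges are removed: ASA grade must be 1, 2 or 3;
age must lie in [30, 100] years; BMI in [15, 55] kg/m^2 (all bounds
inclusive). Rejection is reported as data — a :class:`FilterReport` with a
reason code per rejected record — never as an exception.

Death and revision are modelled as separate cause-specific processes; before
fitting either one, the competing event is recoded as censoring at its
observed time (:func:`recode_competing_event`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import Term, encode_table, schema_names
from .errors import ValidationError

__all__ = [
    "SURGERY_GROUPS",
    "PatientRecord",
    "FilterReason",
    "FilterReport",
    "apply_filters",
    "recode_competing_event",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "DEFAULT_COMMUNITY_SCHEMA",
]

SURGERY_GROUPS = ("hip", "total_knee", "patellofemoral", "unicompartmental")
_KNEE_GROUPS = ("total_knee", "patellofemoral", "unicompartmental")

ASA_ALLOWED = (1, 2, 3)
AGE_RANGE = (30.0, 100.0)
BMI_RANGE = (15.0, 55.0)

#: Community-facing covariates: biometrics a patient can self-report.
DEFAULT_COMMUNITY_SCHEMA: tuple[Term, ...] = (
    Term("age", center=68.0, scale=10.0),
    Term("sex", kind="categorical", reference="male", levels=("female",)),
    Term("bmi", center=29.0, scale=5.0),
    Term("asa", kind="categorical", reference="1", levels=("2", "3")),
)


@dataclass
class PatientRecord:
    """One surgical episode: covariates, outcomes and follow-up.

    ``joint`` is derived from ``surgery_group`` when omitted; if supplied it
    must be consistent (hip group <-> hip joint, knee groups <-> knee).
    Fields left as ``None`` mean "missing" and trigger the completeness
    filter rather than an error.
    """

    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    asa: int | None = None
    surgery_group: str | None = None
    joint: str | None = None
    prom_pre: int | None = None
    prom_post: int | None = None
    time_years: float | None = None
    death: int | None = None
    revision: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.surgery_group is not None and self.surgery_group not in SURGERY_GROUPS:
            raise ValidationError(
                f"unknown surgery_group {self.surgery_group!r}; "
                f"expected one of {SURGERY_GROUPS}"
            )
        derived = None
        if self.surgery_group == "hip":
            derived = "hip"
        elif self.surgery_group in _KNEE_GROUPS:
            derived = "knee"
        if self.joint is None:
            self.joint = derived
        elif derived is not None and self.joint != derived:
            raise ValidationError(
                f"joint {self.joint!r} inconsistent with surgery_group "
                f"{self.surgery_group!r}"
            )


class FilterReason(str, enum.Enum):
    INCOMPLETE = "incomplete"
    ASA_OUT_OF_RANGE = "asa_out_of_range"
    AGE_OUT_OF_RANGE = "age_out_of_range"
    BMI_OUT_OF_RANGE = "bmi_out_of_range"


#: Fields that must be present for a record to count as complete.
REQUIRED_FIELDS = ("age", "sex", "bmi", "asa", "surgery_group", "prom_pre")


@dataclass
class FilterReport:
    kept: list[PatientRecord]
    rejected: list[tuple[PatientRecord, FilterReason]]

    @property
    def counts(self) -> dict[str, int]:
        c = {reason.value: 0 for reason in FilterReason}
        for _, reason in self.rejected:
            c[reason.value] += 1
        return c

    def to_dict(self) -> dict:
        return {
            "n_input": len(self.kept) + len(self.rejected),
            "n_kept": len(self.kept),
            "n_rejected": len(self.rejected),
            "rejected_by_reason": self.counts,
        }


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _classify(record: PatientRecord,
              required: tuple[str, ...]) -> FilterReason | None:
    # Rule order fixes the reason code when several rules fail:
    # completeness, then ASA, then age, then BMI.
    for name in required:
        if _missing(getattr(record, name, None) if hasattr(record, name)
                    else record.extras.get(name)):
            return FilterReason.INCOMPLETE
    if int(record.asa) not in ASA_ALLOWED:
        return FilterReason.ASA_OUT_OF_RANGE
    if not (AGE_RANGE[0] <= float(record.age) <= AGE_RANGE[1]):
        return FilterReason.AGE_OUT_OF_RANGE
    if not (BMI_RANGE[0] <= float(record.bmi) <= BMI_RANGE[1]):
        return FilterReason.BMI_OUT_OF_RANGE
    return None


def apply_filters(records, required: tuple[str, ...] = REQUIRED_FIELDS) -> FilterReport:
    """Partition records into kept and rejected-with-reason.

    Every input record appears exactly once across the two lists; the first
    failing rule (completeness, ASA, age, BMI — in that order) determines the
    reason code.
    """
    kept: list[PatientRecord] = []
    rejected: list[tuple[PatientRecord, FilterReason]] = []
    for rec in records:
        reason = _classify(rec, required)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return FilterReport(kept=kept, rejected=rejected)


def recode_competing_event(records, target_event: str,
                           schema: tuple[Term, ...] = DEFAULT_COMMUNITY_SCHEMA):
    """Build a :class:`~jointrisk.survival.SurvivalDataset` for one event.

    ``target_event`` is ``"death"`` or ``"revision"``. The record's single
    follow-up time is kept; the event indicator is 1 only when the target
    event occurred, so a record where only the competing event happened
    becomes a censored observation at that event's time. When both events are
    flagged at the same recorded time the target event wins.
    """
    from .survival import SurvivalDataset  # local import to avoid a cycle

    if target_event not in ("death", "revision"):
        raise ValidationError(f"target_event must be 'death' or 'revision', "
                              f"got {target_event!r}")
    records = list(records)
    times = []
    events = []
    for rec in records:
        if _missing(rec.time_years) or _missing(rec.death) or _missing(rec.revision):
            raise ValidationError(
                "records must carry time_years and both event indicators"
            )
        times.append(float(rec.time_years))
        events.append(int(getattr(rec, target_event)))
    X = encode_table(records, schema)
    return SurvivalDataset(
        X=X,
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        names=schema_names(schema),
    )


_CORE_COLUMNS = (
    "age", "sex", "bmi", "asa", "surgery_group",
    "prom_pre", "prom_post", "time_years", "death", "revision",
)
_INT_COLUMNS = ("asa", "prom_pre", "prom_post", "death", "revision")


def records_to_frame(records) -> pd.DataFrame:
    """Flatten records (extras included) into a cohort table."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in _CORE_COLUMNS}
        row.update(rec.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    extra_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    for _, row in df.iterrows():
        kwargs = {}
        for c in _CORE_COLUMNS:
            if c not in df.columns:
                continue
            v = row[c]
            if pd.isna(v):
                v = None
            elif c in _INT_COLUMNS:
                v = int(v)
            elif c in ("sex", "surgery_group"):
                v = str(v)
            else:
                v = float(v)
            kwargs[c] = v
        extras = {c: (None if pd.isna(row[c]) else row[c]) for c in extra_cols}
        records.append(PatientRecord(**kwargs, extras=extras))
    return records


def read_cohort(path) -> list[PatientRecord]:
    """Read a comma-separated cohort table (header row, empty = missing)."""
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_cohort(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)
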