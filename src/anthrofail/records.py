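"""Child anthropometry records, WHO plausibility flagging, and the exclusion pipeline.

A :class:`ChildRecord` carries the three WHO growth-standard z-scores
(height-for-age HAZ, weight-for-age WAZ, weight-for-height WHZ) together with
the demographic and complex-survey design fields found in DHS-style child
recode files.  Records are screened in a fixed stage order before analysis:
missing height/weight first, then (optionally) implausible height and age,
and finally z-scores flagged outside the WHO plausibility limits
(HAZ in [-6, +6], WAZ in [-6, +5], WHZ in [-5, +5]).  Each excluded record is
attributed to exactly one reason — the first stage it fails — so the
resulting :class:`ExclusionReport` always balances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "ChildRecord",
    "PlausibilityLimits",
    "ExclusionReport",
    "flag_zscores",
    "apply_exclusion_pipeline",
    "read_records_csv",
    "write_records_csv",
    "records_to_frame",
    "frame_to_records",
]

#: Mean Gregorian month length, used when day-based age bounds are configured.
DAYS_PER_MONTH = 30.4375

#: Exclusion reasons in pipeline stage order.
EXCLUSION_REASONS = (
    "missing_anthropometry",
    "implausible_height",
    "implausible_age",
    "missing_zscore",
    "flagged_haz",
    "flagged_waz",
    "flagged_whz",
)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class ChildRecord:
    """One child's z-scores, demographics, and survey design fields.

    Missing numeric values are represented as ``None``.  ``survey_weight``
    defaults to 1 (self-weighting sample).
    """

    id: str
    haz: float | None = None
    waz: float | None = None
    whz: float | None = None
    age_months: float | None = None
    sex: str = "unknown"
    height_cm: float | None = None
    weight_kg: float | None = None
    survey_weight: float = 1.0
    stratum: str | None = None
    psu: str | None = None

    def __post_init__(self) -> None:
        if self.survey_weight is None:
            self.survey_weight = 1.0
        if self.survey_weight < 0:
            raise ValueError(f"survey_weight must be >= 0, got {self.survey_weight}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be 'male', 'female' or 'unknown', got {self.sex!r}")

    @property
    def has_anthropometry(self) -> bool:
        return not (_is_missing(self.height_cm) or _is_missing(self.weight_kg))

    @property
    def has_zscores(self) -> bool:
        return not any(_is_missing(z) for z in (self.haz, self.waz, self.whz))


@dataclass(frozen=True)
class PlausibilityLimits:
    """WHO z-score flagging bounds, plus optional height/age screens.

    The z-score bounds are closed intervals: values exactly at a limit are
    retained, values strictly beyond it are flagged as biologically
    implausible.  Height and age bounds are DHS-internal screens with no
    published values; they default to ``None`` (stage skipped).
    """

    haz_lo: float = -6.0
    haz_hi: float = 6.0
    waz_lo: float = -6.0
    waz_hi: float = 5.0
    whz_lo: float = -5.0
    whz_hi: float = 5.0
    height_lo_cm: float | None = None
    height_hi_cm: float | None = None
    age_lo_days: float | None = None
    age_hi_days: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.haz_lo, self.haz_hi),
            (self.waz_lo, self.waz_hi),
            (self.whz_lo, self.whz_hi),
        ):
            if not lo < hi:
                raise ValueError(f"plausibility bounds must satisfy lo < hi, got [{lo}, {hi}]")


@dataclass
class ExclusionReport:
    """Per-reason exclusion counts for one pipeline run.

    Invariant: ``input_count == retained_count + sum(counts.values())``;
    each record is counted once, at the first stage it fails.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in EXCLUSION_REASONS}
    )
    retained_count: int = 0
    input_count: int = 0

    @property
    def excluded_count(self) -> int:
        return sum(self.counts.values())

    def balances(self) -> bool:
        return self.input_count == self.retained_count + self.excluded_count

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            **self.counts,
        }


def flag_zscores(record: ChildRecord, limits: PlausibilityLimits | None = None) -> set[str]:
    """Return the subset of ``{flagged_haz, flagged_waz, flagged_whz}`` whose
    z-score exists and lies strictly outside its plausibility interval.

    Boundary values (e.g. HAZ exactly −6) are *not* flagged; missing z-scores
    are not flagged either (they are handled as a separate exclusion reason).
    """
    if limits is None:
        limits = PlausibilityLimits()
    flags: set[str] = set()
    for name, z, lo, hi in (
        ("flagged_haz", record.haz, limits.haz_lo, limits.haz_hi),
        ("flagged_waz", record.waz, limits.waz_lo, limits.waz_hi),
        ("flagged_whz", record.whz, limits.whz_lo, limits.whz_hi),
    ):
        if not _is_missing(z) and (z < lo or z > hi):
            flags.add(name)
    return flags


def _exclusion_reason(record: ChildRecord, limits: PlausibilityLimits) -> str | None:
    """First failing stage for ``record``, or None if it is retained."""
    # Stage 1: height/weight not measured.
    if not record.has_anthropometry:
        return "missing_anthropometry"
    # Stage 2: height out of plausible limits (only when bounds configured).
    if not _is_missing(record.height_cm):
        if limits.height_lo_cm is not None and record.height_cm < limits.height_lo_cm:
            return "implausible_height"
        if limits.height_hi_cm is not None and record.height_cm > limits.height_hi_cm:
            return "implausible_height"
    # Stage 3: age out of plausible limits (bounds given in days).
    if not _is_missing(record.age_months):
        age_days = record.age_months * DAYS_PER_MONTH
        if limits.age_lo_days is not None and age_days < limits.age_lo_days:
            return "implausible_age"
        if limits.age_hi_days is not None and age_days > limits.age_hi_days:
            return "implausible_age"
    # Stage 4: z-score screen — missing first, then flags in HAZ/WAZ/WHZ order.
    if not record.has_zscores:
        return "missing_zscore"
    flags = flag_zscores(record, limits)
    for name in ("flagged_haz", "flagged_waz", "flagged_whz"):
        if name in flags:
            return name
    return None


def apply_exclusion_pipeline(
    records: Iterable[ChildRecord],
    limits: PlausibilityLimits | None = None,
) -> tuple[list[ChildRecord], ExclusionReport]:
    """Screen ``records`` in fixed stage order; return retained records and a
    balanced :class:`ExclusionReport`.

    Every retained record has height/weight present and all three z-scores
    within the plausibility limits; running the pipeline on its own retained
    output excludes nothing (idempotence).
    """
    if limits is None:
        limits = PlausibilityLimits()
    report = ExclusionReport()
    retained: list[ChildRecord] = []
    for record in records:
        report.input_count += 1
        reason = _exclusion_reason(record, limits)
        if reason is None:
            retained.append(record)
        else:
            report.counts[reason] += 1
    report.retained_count = len(retained)
    assert report.balances()
    return retained, report


# ---------------------------------------------------------------------------
# CSV interchange

_REQUIRED_COLUMNS = ("id", "haz", "waz", "whz")
_OPTIONAL_COLUMNS = (
    "age_months",
    "sex",
    "height_cm",
    "weight_kg",
    "survey_weight",
    "stratum",
    "psu",
)
_NUMERIC_FIELDS = ("haz", "waz", "whz", "age_months", "height_cm", "weight_kg", "survey_weight")
_STRING_FIELDS = ("id", "stratum", "psu")


def records_to_frame(records: Sequence[ChildRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the canonical column order."""
    columns = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
    data = {c: [getattr(r, c) for r in records] for c in columns}
    return pd.DataFrame(data, columns=list(columns))


def frame_to_records(frame: pd.DataFrame) -> list[ChildRecord]:
    """Build records from a DataFrame carrying the canonical columns."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for name in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS:
            if name not in frame.columns:
                continue
            value = getattr(row, name)
            if name in _NUMERIC_FIELDS:
                value = None if pd.isna(value) else float(value)
                if name == "survey_weight" and value is None:
                    value = 1.0
            elif name == "sex":
                value = "unknown" if pd.isna(value) else str(value)
            else:  # string-ish identifiers
                value = None if pd.isna(value) else str(value)
            kwargs[name] = value
        if kwargs.get("id") is None:
            raise ValueError("record id may not be missing")
        records.append(ChildRecord(**kwargs))
    return records


def read_records_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    scale: Mapping[str, float] | None = None,
) -> list[ChildRecord]:
    """Read child records from a UTF-8 CSV with a header row.

    Required columns: ``id, haz, waz, whz``; optional: ``age_months, sex,
    height_cm, weight_kg, survey_weight, stratum, psu``.  Missing values are
    empty fields.

    ``column_map`` maps canonical field names to source column names so that
    survey-format files can be ingested without renaming, e.g. the DHS child
    recode mapping ``{"haz": "HW70", "waz": "HW71", "whz": "HW72",
    "survey_weight": "v005"}`` with ``scale={"haz": 0.01, "waz": 0.01,
    "whz": 0.01, "survey_weight": 1e-6}`` (DHS stores z-scores ×100 and
    weights ×10^6).
    """
    frame = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items() if src in frame.columns}
        frame = frame.rename(columns=rename)
    if scale:
        for name, factor in scale.items():
            if name in frame.columns:
                frame[name] = pd.to_numeric(frame[name], errors="coerce") * factor
    return frame_to_records(frame)


def write_records_csv(records: Sequence[ChildRecord], path) -> None:
    """Write records as UTF-8 CSV with the canonical header; missing values
    become empty fields."""
    records_to_frame(records).to_csv(path, index=False)
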