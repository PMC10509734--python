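"""Cohort construction: new-case identification from longitudinal records.

A *new case* is a patient whose earliest colorectal cancer (CRC, ICD-10
C18-C21) admission falls in the diagnosis year with no CRC code in the
preceding washout period (default 5 years).  Inclusion further requires age
>= 18 at diagnosis, consistent sex across admissions, a recorded region, and
no bare cancer-history code (Z08, Z51.0, Z51.1, Z85) in the look-back
without an accompanying primary malignancy of known site.  The *index
hospitalization* is the earliest admission at, or within 4 weeks (28 days,
both endpoints inclusive) after, the first CRC diagnosis date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import icd

__all__ = [
    "HospitalizationRecord",
    "PatientTimeline",
    "CohortEntry",
    "ExclusionReason",
    "ExclusionLog",
    "CohortConfig",
    "MissingIndexError",
    "records_from_frame",
    "build_timelines",
    "identify_new_cases",
    "find_index_admission",
    "classify_cancer_site",
    "age_band",
    "AGE_BANDS",
]

AGE_BANDS = ("18-49", "50-59", "60-69", "70-79", "80+")

#: History-of-malignancy codes flagged in the exclusion flow (normalized,
#: dot-free).  Z08 follow-up exam, Z51.0 radiotherapy, Z51.1 chemotherapy,
#: Z85 personal history of malignant neoplasm.
HISTORY_CODES = ("Z08", "Z510", "Z511", "Z85")


def age_band(age: float) -> str:
    """Age band at diagnosis, per the study's stratification."""
    if age < 18:
        raise ValueError(f"age band undefined below 18: {age}")
    if age < 50:
        return "18-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    if age < 80:
        return "70-79"
    return "80+"


@dataclass(frozen=True)
class HospitalizationRecord:
    """One inpatient admission with up to 16 ICD-10 diagnosis codes."""

    patient_id: str
    sex: str  # "male" | "female"
    age_at_admission: int
    region: str | None  # "urban" | "rural" | "unknown" | None (missing)
    admit_date: dt.date
    discharge_date: dt.date
    diagnoses: tuple[str, ...]  # principal first, normalized dot-free codes

    def __post_init__(self) -> None:
        if self.discharge_date < self.admit_date:
            raise ValueError("discharge before admission")
        if not self.diagnoses:
            raise ValueError("diagnoses must be non-empty")

    @property
    def stems(self) -> tuple[str, ...]:
        return tuple(icd.stem(c) for c in self.diagnoses)

    def has_crc(self) -> bool:
        return any(icd.is_crc(c) for c in self.diagnoses)


@dataclass
class PatientTimeline:
    """All admissions of one patient, sorted by admit date (ties by discharge)."""

    patient_id: str
    records: list[HospitalizationRecord]

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.admit_date, r.discharge_date)
        )
        if any(r.patient_id != self.patient_id for r in self.records):
            raise ValueError("mixed patient ids in timeline")


@dataclass(frozen=True)
class CohortEntry:
    """A confirmed new CRC case with its index admission and subgroup labels."""

    patient_id: str
    first_crc_date: dt.date
    index_admission: HospitalizationRecord
    age_at_diagnosis: int
    sex: str
    region: str | None
    cancer_site: str  # colon | rectum | anus | multiple
    age_band: str


class ExclusionReason(str, Enum):
    PREVALENT_CRC = "prevalent_crc"
    UNDER_18 = "under_18"
    NONRESIDENT = "nonresident"
    INCOMPLETE = "incomplete"
    SEX_CONFLICT = "sex_conflict"
    HISTORY_WITHOUT_SITE = "history_without_site"
    # Patients with no CRC code at all, or whose first CRC falls outside the
    # diagnosis year on the late side; needed so that cohort + exclusions
    # partition the input exactly.
    NO_CRC_IN_YEAR = "no_crc_in_year"


@dataclass(frozen=True)
class ExclusionLog:
    patient_id: str
    reason: ExclusionReason
    detail: str = ""


class MissingIndexError(Exception):
    """No admission found within the index window after first CRC diagnosis."""


@dataclass
class CohortConfig:
    """Tunable thresholds of the cohort stage.

    washout_days: CRC-free period required before the first CRC code
        (5 years = 1826 days, leap-safe day arithmetic).
    index_window_days: admissions up to this many days after the first CRC
        date qualify as the index hospitalization (endpoints inclusive).
    sex_specific_codes: 3-digit stems only valid for one sex; a conflict with
        the recorded sex excludes the patient.
    require_region: when True, a missing (None/empty) region excludes the
        patient as nonresident; the recorded value "unknown" still passes.
    """

    washout_days: int = 1826
    index_window_days: int = 28
    sex_specific_codes: Mapping[str, str] = field(
        default_factory=lambda: {"N40": "male", "N80": "female"}
    )
    require_region: bool = True


# ---------------------------------------------------------------------------
# parsing and timeline assembly

_DX_COLS = ["dx_principal"] + [f"dx_{i}" for i in range(2, 17)]


def records_from_frame(
    df: pd.DataFrame,
) -> tuple[list[HospitalizationRecord], list[ExclusionLog]]:
    """Parse a record table; malformed rows become ``incomplete`` exclusions."""
    records: list[HospitalizationRecord] = []
    exclusions: list[ExclusionLog] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            codes = []
            for col in _DX_COLS:
                val = d.get(col)
                if val is None or (isinstance(val, float) and pd.isna(val)):
                    continue
                sval = str(val).strip()
                if sval:
                    codes.append(icd.normalize(sval))
            region = d.get("region")
            if region is not None and (pd.isna(region) or str(region) == ""):
                region = None
            records.append(
                HospitalizationRecord(
                    patient_id=str(d["patient_id"]),
                    sex=str(d["sex"]),
                    age_at_admission=int(d["age_at_admission"]),
                    region=None if region is None else str(region),
                    admit_date=_as_date(d["admit_date"]),
                    discharge_date=_as_date(d["discharge_date"]),
                    diagnoses=tuple(codes),
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            exclusions.append(
                ExclusionLog(
                    patient_id=str(d.get("patient_id", "?")),
                    reason=ExclusionReason.INCOMPLETE,
                    detail=f"malformed record: {exc}",
                )
            )
    return records, exclusions


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value)[:10])


def build_timelines(
    records: Iterable[HospitalizationRecord],
) -> list[PatientTimeline]:
    """Group records by patient and sort; output order is sorted by id."""
    by_patient: dict[str, list[HospitalizationRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    return [
        PatientTimeline(pid, recs) for pid, recs in sorted(by_patient.items())
    ]


# ---------------------------------------------------------------------------
# inclusion / exclusion flow

def find_index_admission(
    timeline: PatientTimeline,
    first_crc_date: dt.date,
    window_days: int = 28,
) -> HospitalizationRecord:
    """Earliest admission with admit date in [first_crc, first_crc + window]."""
    hi = first_crc_date + dt.timedelta(days=window_days)
    for rec in timeline.records:  # already date-sorted
        if first_crc_date <= rec.admit_date <= hi:
            return rec
    raise MissingIndexError(
        f"{timeline.patient_id}: no admission within {window_days} days "
        f"of first CRC diagnosis {first_crc_date}"
    )


def classify_cancer_site(codes: Iterable[str]) -> str:
    """Map CRC codes at first diagnosis to colon / rectum / anus / multiple.

    C18 -> colon; C19 (rectosigmoid junction) and C20 -> rectum; C21 -> anus.
    Codes from more than one of these groups -> multiple.
    """
    groups = set()
    for code in codes:
        s = icd.stem(code)
        if s == "C18":
            groups.add("colon")
        elif s in ("C19", "C20"):
            groups.add("rectum")
        elif s == "C21":
            groups.add("anus")
    if not groups:
        raise ValueError("no CRC code among inputs")
    return groups.pop() if len(groups) == 1 else "multiple"


def _sex_conflict(
    timeline: PatientTimeline, config: CohortConfig
) -> str | None:
    sexes = {r.sex for r in timeline.records}
    if len(sexes) > 1:
        return f"multiple sex values recorded: {sorted(sexes)}"
    sex = sexes.pop()
    for rec in timeline.records:
        for s in rec.stems:
            required = config.sex_specific_codes.get(s)
            if required is not None and required != sex:
                return f"{required}-only code {s} recorded for {sex} patient"
    return None


_KNOWN_SITE_PRIMARY = [("C00", "C75"), ("C81", "C97")]


def _history_without_site(
    timeline: PatientTimeline, first_crc_date: dt.date
) -> str | None:
    """Bare cancer-history code in the pre-diagnosis period.

    A Z08/Z51.0/Z51.1/Z85 code before the first CRC admission is acceptable
    only when accompanied (anywhere in that prior history) by a primary
    malignancy code with a known site (C00-C75, C81-C97); otherwise the
    patient may be a relapsed case of unknown primary and is excluded.
    """
    prior = [r for r in timeline.records if r.admit_date < first_crc_date]
    hist = [
        c
        for r in prior
        for c in r.diagnoses
        if c[:4] in HISTORY_CODES or c[:3] in HISTORY_CODES
    ]
    if not hist:
        return None
    for rec in prior:
        for s in rec.stems:
            if any(lo <= s <= hi for lo, hi in _KNOWN_SITE_PRIMARY):
                return None
    return f"history code {hist[0]} without known-site primary malignancy"


def identify_new_cases(
    timelines: Sequence[PatientTimeline],
    diagnosis_year: int,
    washout_years: int = 5,
    config: CohortConfig | None = None,
) -> tuple[list[CohortEntry], list[ExclusionLog]]:
    """Apply the inclusion/exclusion flow; returns (cohort, exclusion log).

    Checks run in a fixed order and the first failure wins: prevalent CRC,
    under 18, nonresident, incomplete (no index admission), sex conflict,
    bare history code.  Every input patient lands in exactly one output.
    """
    config = config or CohortConfig()
    washout_days = round(washout_years * 365.25)
    cohort: list[CohortEntry] = []
    exclusions: list[ExclusionLog] = []

    for tl in timelines:
        crc_recs = [r for r in tl.records if r.has_crc()]
        if not crc_recs:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.NO_CRC_IN_YEAR,
                             "no C18-C21 code in record")
            )
            continue
        first = crc_recs[0]
        first_date = first.admit_date
        if first_date.year < diagnosis_year:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.PREVALENT_CRC,
                             f"first CRC admission {first_date}")
            )
            continue
        if first_date.year > diagnosis_year:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.NO_CRC_IN_YEAR,
                             f"first CRC admission {first_date}")
            )
            continue
        # CRC-free washout before the first CRC code (vacuous when `first`
        # really is earliest, kept for defense against unsorted inputs).
        lo = first_date - dt.timedelta(days=washout_days)
        if any(
            r.admit_date < first_date and r.admit_date >= lo for r in crc_recs
        ):
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.PREVALENT_CRC,
                             "CRC code inside washout period")
            )
            continue
        if first.age_at_admission < 18:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.UNDER_18,
                             f"age {first.age_at_admission} at diagnosis")
            )
            continue
        if config.require_region and all(
            r.region is None for r in tl.records
        ):
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.NONRESIDENT,
                             "no recorded region")
            )
            continue
        try:
            index = find_index_admission(
                tl, first_date, config.index_window_days
            )
        except MissingIndexError as exc:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.INCOMPLETE,
                             str(exc))
            )
            continue
        conflict = _sex_conflict(tl, config)
        if conflict is not None:
            exclusions.append(
                ExclusionLog(tl.patient_id, ExclusionReason.SEX_CONFLICT,
                             conflict)
            )
            continue
        bare = _history_without_site(tl, first_date)
        if bare is not None:
            exclusions.append(
                ExclusionLog(tl.patient_id,
                             ExclusionReason.HISTORY_WITHOUT_SITE, bare)
            )
            continue
        site_codes = [
            c
            for r in tl.records
            if r.admit_date == first_date
            for c in r.diagnoses
            if icd.is_crc(c)
        ]
        cohort.append(
            CohortEntry(
                patient_id=tl.patient_id,
                first_crc_date=first_date,
                index_admission=index,
                age_at_diagnosis=first.age_at_admission,
                sex=first.sex,
                region=first.region,
                cancer_site=classify_cancer_site(site_codes),
                age_band=age_band(first.age_at_admission),
            )
        )
    return cohort, exclusions


def cohort_frame(cohort: Sequence[CohortEntry]) -> pd.DataFrame:
    """Cohort as a table, one row per included patient (sorted by id)."""
    rows = [
        {
            "patient_id": e.patient_id,
            "first_crc_date": e.first_crc_date.isoformat(),
            "index_admit_date": e.index_admission.admit_date.isoformat(),
            "age_at_diagnosis": e.age_at_diagnosis,
            "age_band": e.age_band,
            "sex": e.sex,
            "region": e.region,
            "cancer_site": e.cancer_site,
        }
        for e in sorted(cohort, key=lambda e: e.patient_id)
    ]
    return pd.DataFrame(rows)


def exclusion_frame(exclusions: Sequence[ExclusionLog]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "reason": e.reason.value,
            "detail": e.detail,
        }
        for e in sorted(exclusions, key=lambda e: e.patient_id)
    ]
    return pd.DataFrame(rows)
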