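"""Chronic-comorbidity extraction over the look-back window.

For each cohort entry, all admissions from ``lookback_years`` before the
first CRC diagnosis up to the diagnosis date, plus the index admission, are
scanned.  Diagnosis codes are truncated to 3 digits and filtered:

* only chronic codes are kept (Chronic Condition Indicator-style lookup,
  packaged as an editable text file);
* codes from the excluded ICD-10 chapters (default XV-XXII, i.e. first
  letter O-Z: pregnancy/perinatal, symptoms, injury, external causes,
  health-status contact) are dropped;
* the CRC codes C18-C21 themselves are dropped;
* configured CRC-complication codes (secondary malignancy, anemias,
  marasmus, agranulocytosis, metabolic disorders, intestinal obstruction)
  are dropped when they appear *only* at the index admission — a prior
  look-back occurrence keeps them.

The result is a binary patients x diseases incidence matrix.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import icd
from .cohort import CohortEntry, PatientTimeline

__all__ = [
    "ChronicMap",
    "ExtractionSpec",
    "ComorbidityMatrix",
    "load_default_chronic_map",
    "scan_lookback",
    "build_matrix",
    "comorbidity_count_distribution",
]


class ChronicMap:
    """Total chronic/not-chronic classifier over 3-digit ICD-10 stems.

    Codes not present in the table are classified not chronic and collected
    in :attr:`unknown_codes` for audit.
    """

    def __init__(self, chronic_stems: Iterable[str]) -> None:
        self._chronic = frozenset(icd.stem(c) for c in chronic_stems)
        self.unknown_codes: set[str] = set()

    def __contains__(self, code: str) -> bool:
        return self.is_chronic(code)

    def __len__(self) -> int:
        return len(self._chronic)

    def is_chronic(self, code: str) -> bool:
        s = icd.stem(code)
        if s in self._chronic:
            return True
        self.unknown_codes.add(s)
        return False

    @classmethod
    def from_file(cls, path: str | Path) -> "ChronicMap":
        stems: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                stems.extend(_expand_range(line))
        return cls(stems)


def _expand_range(token: str) -> list[str]:
    """Expand 'E10-E14' to the inclusive list of 3-digit stems."""
    if "-" not in token:
        return [icd.normalize(token)]
    lo, hi = (icd.normalize(t) for t in token.split("-", 1))
    if lo[0] != hi[0]:
        raise ValueError(f"range must stay within one letter: {token}")
    return [f"{lo[0]}{i:02d}" for i in range(int(lo[1:3]), int(hi[1:3]) + 1)]


def load_default_chronic_map() -> ChronicMap:
    """The packaged chronic-condition classification."""
    ref = resources.files("pcnkit").joinpath("data/chronic3.txt")
    with resources.as_file(ref) as path:
        return ChronicMap.from_file(path)


def _default_index_exclusions() -> frozenset[str]:
    stems: list[str] = []
    for token in ("C77-C79", "D50-D64", "E41", "D70", "E70-E90", "K56"):
        stems.extend(_expand_range(token))
    return frozenset(stems)


@dataclass
class ExtractionSpec:
    """Parameters of the look-back scan.

    lookback_years: horizon before the first CRC diagnosis (5 default;
        3 for the sensitivity variant). Converted to days at 365.25 d/yr.
    excluded_chapter_letters: first letters of excluded ICD-10 chapters
        (default O-Z = chapters XV-XXII).
    index_exclusion_codes: 3-digit stems treated as CRC/treatment
        complications when first seen at the index admission.
    """

    lookback_years: int = 5
    excluded_chapter_letters: frozenset[str] = frozenset("OPQRSTUVWXYZ")
    index_exclusion_codes: frozenset[str] = field(
        default_factory=_default_index_exclusions
    )

    def __post_init__(self) -> None:
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")

    @property
    def lookback_days(self) -> int:
        return round(self.lookback_years * 365.25)


@dataclass
class ComorbidityMatrix:
    """Binary patients x chronic-disease incidence matrix."""

    data: pd.DataFrame  # index: patient ids, columns: 3-digit codes, 0/1

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts_per_patient(self) -> pd.Series:
        return self.data.sum(axis=1)

    def column_counts(self) -> pd.Series:
        """n_a per disease (column sums)."""
        return self.data.sum(axis=0)

    @property
    def n(self) -> int:
        return len(self.data)


def scan_lookback(
    entry: CohortEntry,
    timeline: PatientTimeline,
    spec: ExtractionSpec,
    chronic: ChronicMap,
) -> set[str]:
    """Chronic comorbidity stems of one patient after all filters."""
    lo = entry.first_crc_date - dt.timedelta(days=spec.lookback_days)
    hi = entry.first_crc_date
    index_rec = entry.index_admission

    lookback_stems: set[str] = set()
    for rec in timeline.records:
        if lo <= rec.admit_date <= hi and rec is not index_rec:
            lookback_stems.update(rec.stems)
    index_stems = set(index_rec.stems)

    candidates = lookback_stems | index_stems
    out: set[str] = set()
    for s in candidates:
        if s in icd.CRC_STEMS:
            continue
        if s[0] in spec.excluded_chapter_letters:
            continue
        if not chronic.is_chronic(s):
            continue
        if s in spec.index_exclusion_codes and s not in lookback_stems:
            continue  # complication first seen at the index admission
        out.add(s)
    return out


def build_matrix(
    cohort: Sequence[CohortEntry],
    timelines: Mapping[str, PatientTimeline] | Sequence[PatientTimeline],
    spec: ExtractionSpec | None = None,
    chronic: ChronicMap | None = None,
) -> ComorbidityMatrix:
    """Assemble the incidence matrix (rows/columns sorted, deterministic)."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    spec = spec or ExtractionSpec()
    chronic = chronic if chronic is not None else load_default_chronic_map()
    if not isinstance(timelines, Mapping):
        timelines = {tl.patient_id: tl for tl in timelines}

    sets: dict[str, set[str]] = {}
    for entry in cohort:
        sets[entry.patient_id] = scan_lookback(
            entry, timelines[entry.patient_id], spec, chronic
        )
    patients = sorted(sets)
    diseases = sorted(set().union(*sets.values())) if sets else []
    arr = np.zeros((len(patients), len(diseases)), dtype=np.int8)
    col = {d: j for j, d in enumerate(diseases)}
    for i, pid in enumerate(patients):
        for d in sets[pid]:
            arr[i, col[d]] = 1
    return ComorbidityMatrix(
        pd.DataFrame(arr, index=patients, columns=diseases)
    )


def comorbidity_count_distribution(matrix: ComorbidityMatrix) -> pd.DataFrame:
    """Patients per comorbidity-count bin (0, 1, ..., 5, >=6), with percent."""
    counts = matrix.counts_per_patient
    bins = ["0", "1", "2", "3", "4", "5", ">=6"]
    n_per = {b: 0 for b in bins}
    for c in counts:
        n_per[str(int(c)) if c < 6 else ">=6"] += 1
    total = len(counts)
    return pd.DataFrame(
        {
            "n_comorbidities": bins,
            "n": [n_per[b] for b in bins],
            "pct": [100.0 * n_per[b] / total for b in bins],
        }
    )
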