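"""Synthetic longitudinal hospital-discharge records with known ground truth.

The real study data (provincial hospital discharge records, HDRs) are not
public, so this module generates record sets that emulate their structure:
multi-year admission histories per patient, a sentinel colorectal cancer
(CRC) admission in the final study year, subgroup structure (sex, age band,
urban/rural region, cancer site), chronic-disease prevalences that vary by
subgroup and age, and planted pairwise disease associations with a target
odds ratio.  Every patient's latent disease vector and intended cohort
disposition are recorded alongside the records, so every downstream stage
can be tested closed-loop.

Associated pairs are sampled jointly: given the two marginal prevalences
``pa, pb`` and a target odds ratio ``psi``, the joint cell ``p11`` is the
root of the standard quadratic

    psi = p11 * (1 - pa - pb + p11) / ((pa - p11) * (pb - p11))

Pairs in the association spec must be vertex-disjoint; overlapping pairs
would require specifying a full joint distribution and are rejected.

Contaminant patients — near-miss inputs the cohort filters must catch —
are produced by mutating valid patients: a CRC code planted in the first
study year (prevalent case), a bare cancer-history code (Z85) in the
look-back, a flipped sex value on one admission, an under-18 age, or a
CRC-complication code (e.g. K56) injected at the index admission only.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import HospitalizationRecord

__all__ = [
    "DiseaseSpec",
    "AssociationSpec",
    "ContaminationRates",
    "SimulationConfig",
    "RecordSet",
    "InfeasibleAssociationError",
    "joint_prob_from_or",
    "sample_latent_matrix",
    "generate_population",
    "write_records",
    "read_records",
    "read_truth",
    "default_config",
]

LOOKBACK_DAYS = 1826  # 5 years, the look-back horizon the records must fill

_FILLER_ACUTE = ("J06", "A09", "J18", "L03")  # acute codes for admissions
# without any chronic disease; none is chronic or in an excluded analysis set


class InfeasibleAssociationError(ValueError):
    """Marginals and odds ratio admit no valid 2x2 distribution."""

    def __init__(self, pair: tuple[str, str], message: str) -> None:
        self.pair = pair
        super().__init__(f"pair {pair}: {message}")


@dataclass(frozen=True)
class DiseaseSpec:
    """Marginal prevalence model of one 3-digit chronic disease code.

    The cell prevalence is ``base`` multiplied by the relative-risk factors
    of the patient's sex, region, cancer site and age band, clipped to
    [0, 0.95].  A factor of 0 makes the disease sex-specific (etc.).
    """

    code: str
    base: float
    sex_rr: Mapping[str, float] = field(default_factory=dict)
    region_rr: Mapping[str, float] = field(default_factory=dict)
    site_rr: Mapping[str, float] = field(default_factory=dict)
    age_rr: Mapping[str, float] = field(default_factory=dict)

    def prevalence(self, sex: str, region: str, site: str, band: str) -> float:
        p = (
            self.base
            * self.sex_rr.get(sex, 1.0)
            * self.region_rr.get(region, 1.0)
            * self.site_rr.get(site, 1.0)
            * self.age_rr.get(band, 1.0)
        )
        return float(min(max(p, 0.0), 0.95))


@dataclass(frozen=True)
class AssociationSpec:
    code_a: str
    code_b: str
    odds_ratio: float


@dataclass(frozen=True)
class ContaminationRates:
    """Per-patient probabilities of each planted exclusion scenario.

    The first four are mutually exclusive (a patient receives at most one
    mutation); ``index_complication`` is independent and does not exclude
    the patient — it plants a complication code at the index admission only,
    which the comorbidity extraction must ignore.
    """

    prevalent_crc: float = 0.0
    history_without_site: float = 0.0
    sex_conflict: float = 0.0
    under_18: float = 0.0
    index_complication: float = 0.0

    def validate(self) -> None:
        vals = (
            self.prevalent_crc,
            self.history_without_site,
            self.sex_conflict,
            self.under_18,
            self.index_complication,
        )
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("contamination rates must lie in [0, 1]")
        if sum(vals[:4]) > 1:
            raise ValueError("exclusive contamination rates sum above 1")


@dataclass
class SimulationConfig:
    n_patients: int
    seed: int
    study_window: tuple[dt.date, dt.date] = (
        dt.date(2015, 1, 1),
        dt.date(2020, 12, 31),
    )
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.589, "female": 0.411}
    )
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {"rural": 0.540, "urban": 0.457,
                                 "unknown": 0.003}
    )
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: {"colon": 0.441, "rectum": 0.525,
                                 "anus": 0.027, "multiple": 0.007}
    )
    age_band_probs: Mapping[str, float] = field(
        default_factory=lambda: {"18-49": 0.114, "50-59": 0.187,
                                 "60-69": 0.281, "70-79": 0.290,
                                 "80+": 0.128}
    )
    disease_panel: Sequence[DiseaseSpec] = ()
    association_spec: Sequence[AssociationSpec] = ()
    mean_lookback_admissions: float = 2.5  # Poisson mean; index is extra
    contamination: ContaminationRates = field(
        default_factory=ContaminationRates
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        start, end = self.study_window
        if (end - start).days < LOOKBACK_DAYS + 365:
            raise ValueError(
                "study_window must span the look-back horizon plus the "
                "diagnosis year (>= 6 calendar years)"
            )
        for probs in (self.sex_probs, self.region_probs, self.site_probs,
                      self.age_band_probs):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")
        seen: set[str] = set()
        codes = {d.code for d in self.disease_panel}
        for assoc in self.association_spec:
            if assoc.odds_ratio <= 0:
                raise ValueError("odds ratios must be positive")
            if assoc.code_a not in codes or assoc.code_b not in codes:
                raise ValueError(
                    f"association pair ({assoc.code_a}, {assoc.code_b}) "
                    "references a code outside the disease panel"
                )
            for c in (assoc.code_a, assoc.code_b):
                if c in seen:
                    raise ValueError(
                        "association pairs must be vertex-disjoint; "
                        f"code {c} appears in more than one pair"
                    )
                seen.add(c)
        self.contamination.validate()


@dataclass
class PatientTruth:
    patient_id: str
    sex: str
    region: str
    site: str
    age_at_diagnosis: int
    age_band: str
    index_date: dt.date
    diseases: tuple[str, ...]  # latent chronic diseases present
    disposition: str  # "include" or the exclusion reason
    index_complication: str | None = None


@dataclass
class RecordSet:
    """Generated admissions plus the latent truth they were built from."""

    records: list[HospitalizationRecord]
    truth: dict[str, PatientTruth]
    pair_odds_ratios: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


# ---------------------------------------------------------------------------
# correlated-binary machinery

def joint_prob_from_or(pa: float, pb: float, odds_ratio: float,
                       pair: tuple[str, str] = ("a", "b")) -> float:
    """Joint probability P(A=1, B=1) with given marginals and odds ratio.

    Solves psi*(pa-p11)*(pb-p11) = p11*(1-pa-pb+p11) for p11; for psi != 1
    the smaller quadratic root is the valid cell probability.
    """
    if not (0 <= pa <= 1 and 0 <= pb <= 1):
        raise InfeasibleAssociationError(pair, "marginals outside [0, 1]")
    if odds_ratio <= 0:
        raise InfeasibleAssociationError(pair, "odds ratio must be positive")
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return pa * pb  # degenerate margin: association is vacuous
    if odds_ratio == 1.0:
        p11 = pa * pb
    else:
        k = odds_ratio - 1.0
        s = 1.0 + (pa + pb) * k
        disc = s * s - 4.0 * odds_ratio * k * pa * pb
        if disc < 0:
            raise InfeasibleAssociationError(
                pair, f"no real solution for marginals ({pa}, {pb}) at "
                f"odds ratio {odds_ratio}")
        p11 = (s - math.sqrt(disc)) / (2.0 * k)
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise InfeasibleAssociationError(
            pair, f"solution p11={p11:.6g} violates Frechet bounds "
            f"[{lo:.6g}, {hi:.6g}]")
    return float(min(max(p11, lo), hi))


def sample_latent_matrix(
    config: SimulationConfig,
    subgroups: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latent binary disease matrix for patients with known subgroup labels.

    ``subgroups`` needs columns sex, region, site, age_band.  Marginal
    prevalences follow each disease's spec for the patient's cell; pairs in
    the association spec are drawn jointly at the target odds ratio, all
    other diseases independently.
    """
    codes = [d.code for d in config.disease_panel]
    n = len(subgroups)
    prev = np.zeros((n, len(codes)))
    for j, spec in enumerate(config.disease_panel):
        cells: dict[tuple[str, str, str, str], float] = {}
        key_cols = zip(subgroups["sex"], subgroups["region"],
                       subgroups["site"], subgroups["age_band"])
        col = np.empty(n)
        for i, key in enumerate(key_cols):
            if key not in cells:
                cells[key] = spec.prevalence(*key)
            col[i] = cells[key]
        prev[:, j] = col

    out = np.zeros((n, len(codes)), dtype=np.int8)
    paired = set()
    col_of = {c: j for j, c in enumerate(codes)}
    for assoc in config.association_spec:
        ja, jb = col_of[assoc.code_a], col_of[assoc.code_b]
        paired.update((ja, jb))
        pa, pb = prev[:, ja], prev[:, jb]
        p11 = np.array([
            joint_prob_from_or(a, b, assoc.odds_ratio,
                               (assoc.code_a, assoc.code_b))
            for a, b in zip(pa, pb)
        ])
        ua = rng.random(n)
        a = ua < pa
        # conditional P(B=1 | A)
        with np.errstate(divide="ignore", invalid="ignore"):
            pb_given_a = np.where(pa > 0, p11 / pa, 0.0)
            pb_given_not_a = np.where(pa < 1, (pb - p11) / (1 - pa), 0.0)
        ub = rng.random(n)
        b = np.where(a, ub < pb_given_a, ub < pb_given_not_a)
        out[:, ja] = a
        out[:, jb] = b
    for j in range(len(codes)):
        if j not in paired:
            out[:, j] = rng.random(n) < prev[:, j]
    return pd.DataFrame(out, index=subgroups.index, columns=codes)


def _realized_odds_ratios(
    latent: pd.DataFrame,
    subgroups: pd.DataFrame,
    associations: Sequence[AssociationSpec],
) -> dict[tuple[str, str], float]:
    """Realized association per planted pair.

    The target odds ratio is planted *within* each subgroup/age cell, so the
    realized value is the Mantel-Haenszel common odds ratio across those
    strata (the pooled marginal OR is legitimately larger whenever both
    prevalences rise together across cells).
    """
    strata = subgroups.loc[latent.index].apply(tuple, axis=1)
    out: dict[tuple[str, str], float] = {}
    for assoc in associations:
        a = latent[assoc.code_a].to_numpy().astype(bool)
        b = latent[assoc.code_b].to_numpy().astype(bool)
        num = den = 0.0
        for _, idx in strata.groupby(strata).groups.items():
            pos = latent.index.get_indexer(idx)
            ak, bk = a[pos], b[pos]
            nk = len(pos)
            if nk == 0:
                continue
            n11 = int(np.sum(ak & bk))
            n10 = int(np.sum(ak & ~bk))
            n01 = int(np.sum(~ak & bk))
            n00 = nk - n11 - n10 - n01
            num += n11 * n00 / nk
            den += n10 * n01 / nk
        out[(assoc.code_a, assoc.code_b)] = (
            num / den if den > 0 else float("nan")
        )
    return out


# ---------------------------------------------------------------------------
# record assembly

def _draw_categorical(rng, probs: Mapping[str, float], size: int) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


_BAND_RANGES = {"18-49": (18, 49), "50-59": (50, 59), "60-69": (60, 69),
                "70-79": (70, 79), "80+": (80, 94)}


def generate_population(config: SimulationConfig) -> RecordSet:
    """Generate the full synthetic record set (deterministic given the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start, end = config.study_window
    final_year_start = dt.date(end.year, 1, 1)

    subgroups = pd.DataFrame(
        {
            "sex": _draw_categorical(rng, config.sex_probs, n),
            "region": _draw_categorical(rng, config.region_probs, n),
            "site": _draw_categorical(rng, config.site_probs, n),
            "age_band": _draw_categorical(rng, config.age_band_probs, n),
        },
        index=[f"P{i:06d}" for i in range(n)],
    )
    ages = np.array([
        rng.integers(*_BAND_RANGES[b], endpoint=True)
        for b in subgroups["age_band"]
    ])
    latent = sample_latent_matrix(config, subgroups, rng)

    # exclusive contaminant assignment + independent index-complication flag
    rates = config.contamination
    u = rng.random(n)
    kinds = np.full(n, "", dtype=object)
    edges = np.cumsum([rates.prevalent_crc, rates.history_without_site,
                       rates.sex_conflict, rates.under_18])
    names = ["prevalent_crc", "history_without_site", "sex_conflict",
             "under_18"]
    for i in range(n):
        for name, edge in zip(names, edges):
            if u[i] < edge:
                kinds[i] = name
                break
    complication = rng.random(n) < rates.index_complication
    complication_codes = rng.choice(
        ["K56", "D50", "C78", "E41", "D70", "E87"], size=n
    )

    site_principal = {"colon": "C18", "anus": "C21"}
    records: list[HospitalizationRecord] = []
    truth: dict[str, PatientTruth] = {}
    index_day_span = (end - final_year_start).days

    for i, pid in enumerate(subgroups.index):
        sex = str(subgroups.at[pid, "sex"])
        region = str(subgroups.at[pid, "region"])
        site = str(subgroups.at[pid, "site"])
        band = str(subgroups.at[pid, "age_band"])
        age_dx = int(ages[i])
        kind = str(kinds[i])
        if kind == "under_18":
            age_dx = int(rng.integers(5, 18))
            band = "18-49"  # nominal; patient is excluded before banding

        index_date = final_year_start + dt.timedelta(
            days=int(rng.integers(0, index_day_span + 1))
        )
        birth_year = index_date.year - age_dx
        diseases = tuple(
            c for c in latent.columns if latent.at[pid, c] == 1
        )

        n_lookback = int(rng.poisson(config.mean_lookback_admissions))
        if diseases and n_lookback == 0:
            n_lookback = 1
        lb_offsets = np.sort(
            rng.integers(1, LOOKBACK_DAYS + 1, size=n_lookback)
        )[::-1]
        lb_dates = [index_date - dt.timedelta(days=int(o)) for o in lb_offsets]
        lb_dates = [d for d in lb_dates if d >= start]
        if diseases and not lb_dates:
            lb_dates = [max(start, index_date - dt.timedelta(days=200))]
        lb_codes: list[list[str]] = [[] for _ in lb_dates]
        for code in diseases:
            if lb_dates:
                slots = {int(rng.integers(0, len(lb_dates)))}
                if rng.random() < 0.3:  # duplicate coding across admissions
                    slots.add(int(rng.integers(0, len(lb_dates))))
                for s in slots:
                    lb_codes[s].append(code)

        # index admission: sentinel CRC code(s) + diseases coded there too
        if site == "rectum":
            crc_codes = ["C19" if rng.random() < 0.15 else "C20"]
        elif site == "multiple":
            crc_codes = ["C18", "C20"]
        else:
            crc_codes = [site_principal[site]]
        index_codes = list(crc_codes)
        for code in diseases:
            if rng.random() < 0.5:
                index_codes.append(code)

        complication_code: str | None = None
        if complication[i]:
            complication_code = str(complication_codes[i])
            # planted at the index admission only: must not also sit in the
            # look-back, and must not be a latent disease of this patient
            if complication_code not in diseases:
                index_codes.append(complication_code)
            else:
                complication_code = None

        disposition = "include" if kind == "" else kind
        rec_sex = [sex] * (len(lb_dates) + 1)
        rec_dates = list(lb_dates) + [index_date]
        rec_code_lists = lb_codes + [index_codes]

        if kind == "prevalent_crc":
            # CRC admission in the first study year, outside the washout of
            # nothing — it becomes the true first CRC, so the patient is a
            # prevalent (not new) case
            prior_date = start + dt.timedelta(days=int(rng.integers(0, 330)))
            rec_dates.insert(0, prior_date)
            rec_code_lists.insert(0, ["C18"])
            rec_sex.insert(0, sex)
        elif kind == "history_without_site":
            bare = str(rng.choice(["Z85", "Z510", "Z511", "Z08"]))
            if lb_dates:
                rec_code_lists[0] = [
                    c for c in rec_code_lists[0] if not c.startswith("C")
                ] + [bare]
            else:
                rec_dates.insert(0, index_date - dt.timedelta(days=400))
                rec_code_lists.insert(0, [bare])
                rec_sex.insert(0, sex)
        elif kind == "sex_conflict":
            flipped = "female" if sex == "male" else "male"
            if len(rec_dates) == 1:
                rec_dates.insert(0, index_date - dt.timedelta(days=300))
                rec_code_lists.insert(0, [])
                rec_sex.insert(0, sex)
            rec_sex[0] = flipped

        for date, code_list, rsex in zip(rec_dates, rec_code_lists, rec_sex):
            codes = list(dict.fromkeys(code_list))  # dedupe, keep order
            if not codes:
                codes = [str(rng.choice(_FILLER_ACUTE))]
            los = int(rng.integers(2, 15))
            discharge = min(date + dt.timedelta(days=los), end)
            records.append(
                HospitalizationRecord(
                    patient_id=pid,
                    sex=rsex,
                    age_at_admission=max(0, date.year - birth_year),
                    region=region,
                    admit_date=date,
                    discharge_date=discharge,
                    diagnoses=tuple(codes[:16]),
                )
            )

        truth[pid] = PatientTruth(
            patient_id=pid,
            sex=sex,
            region=region,
            site=site,
            age_at_diagnosis=age_dx,
            age_band=band,
            index_date=index_date,
            diseases=diseases,
            disposition=disposition,
            index_complication=complication_code,
        )

    included = [p for p, t in truth.items() if t.disposition == "include"]
    pair_or = _realized_odds_ratios(
        latent.loc[included], subgroups, config.association_spec
    )
    return RecordSet(records=records, truth=truth, pair_odds_ratios=pair_or)


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = (
    ["patient_id", "sex", "age_at_admission", "region", "admit_date",
     "discharge_date", "dx_principal"]
    + [f"dx_{i}" for i in range(2, 17)]
)


def records_to_frame(records: Sequence[HospitalizationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age_at_admission": r.age_at_admission,
            "region": "" if r.region is None else r.region,
            "admit_date": r.admit_date.isoformat(),
            "discharge_date": r.discharge_date.isoformat(),
            "dx_principal": r.diagnoses[0],
        }
        for i, code in enumerate(r.diagnoses[1:16], start=2):
            row[f"dx_{i}"] = code
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_records(rs: RecordSet, path: str | Path,
                  truth_path: str | Path | None = None) -> None:
    """Write the admission table (CSV) and, optionally, the truth (JSONL)."""
    path = Path(path)
    rs.to_frame().to_csv(path, index=False)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            for pid in sorted(rs.truth):
                t = rs.truth[pid]
                fh.write(json.dumps({
                    "patient_id": t.patient_id,
                    "sex": t.sex,
                    "region": t.region,
                    "site": t.site,
                    "age_at_diagnosis": t.age_at_diagnosis,
                    "age_band": t.age_band,
                    "index_date": t.index_date.isoformat(),
                    "diseases": list(t.diseases),
                    "disposition": t.disposition,
                    "index_complication": t.index_complication,
                }) + "\n")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).assign(
        age_at_admission=lambda d: d["age_at_admission"].astype(int)
    )


def read_truth(path: str | Path) -> dict[str, PatientTruth]:
    out: dict[str, PatientTruth] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            out[d["patient_id"]] = PatientTruth(
                patient_id=d["patient_id"],
                sex=d["sex"],
                region=d["region"],
                site=d["site"],
                age_at_diagnosis=d["age_at_diagnosis"],
                age_band=d["age_band"],
                index_date=dt.date.fromisoformat(d["index_date"]),
                diseases=tuple(d["diseases"]),
                disposition=d["disposition"],
                index_complication=d["index_complication"],
            )
    return out


# ---------------------------------------------------------------------------
# default study conditions

def default_panel() -> list[DiseaseSpec]:
    """Default disease panel: prevalences and subgroup effects modelled on
    the chronic conditions most prevalent in newly diagnosed CRC patients."""
    rising = {"18-49": 0.25, "50-59": 0.6, "60-69": 1.0, "70-79": 1.4,
              "80+": 1.7}
    mild = {"18-49": 0.6, "50-59": 0.8, "60-69": 1.0, "70-79": 1.2,
            "80+": 1.3}
    flat: dict[str, float] = {}
    return [
        DiseaseSpec("I10", 0.29, age_rr=mild),
        DiseaseSpec("N40", 0.22, sex_rr={"female": 0.0}, age_rr=rising),
        DiseaseSpec("J44", 0.142, sex_rr={"male": 1.22, "female": 0.67},
                    age_rr=rising),
        DiseaseSpec("E11", 0.125, region_rr={"urban": 1.2, "rural": 0.85},
                    age_rr=mild),
        DiseaseSpec("I25", 0.108, age_rr=rising),
        DiseaseSpec("I70", 0.092, region_rr={"urban": 1.25, "rural": 0.8},
                    age_rr=rising),
        DiseaseSpec("E78", 0.08, region_rr={"urban": 1.35, "rural": 0.75},
                    age_rr=mild),
        DiseaseSpec("I63", 0.07, age_rr=rising),
        DiseaseSpec("I67", 0.067, region_rr={"urban": 1.3, "rural": 0.78},
                    age_rr=rising),
        DiseaseSpec("I50", 0.05, age_rr=rising),
        DiseaseSpec("K21", 0.038, age_rr=flat),
        DiseaseSpec("M47", 0.038, region_rr={"urban": 1.25, "rural": 0.82}),
        DiseaseSpec("E77", 0.036, site_rr={"colon": 1.3, "rectum": 0.78}),
        DiseaseSpec("M81", 0.031, sex_rr={"male": 0.55, "female": 1.7},
                    age_rr=rising),
        DiseaseSpec("I11", 0.030, region_rr={"urban": 1.3, "rural": 0.8},
                    age_rr=mild),
        DiseaseSpec("N19", 0.025, sex_rr={"male": 1.25, "female": 0.7}),
        DiseaseSpec("E04", 0.022, sex_rr={"male": 0.55, "female": 1.6}),
        DiseaseSpec("N18", 0.017, sex_rr={"male": 1.2, "female": 0.75},
                    region_rr={"urban": 1.3, "rural": 0.8}),
        DiseaseSpec("K57", 0.015, region_rr={"urban": 1.5, "rural": 0.6}),
        DiseaseSpec("M17", 0.015, sex_rr={"male": 0.5, "female": 1.75}),
        DiseaseSpec("M10", 0.012, sex_rr={"male": 1.5, "female": 0.3}),
        DiseaseSpec("F41", 0.008, sex_rr={"male": 0.0, "female": 1.6}),
    ]


def default_associations() -> list[AssociationSpec]:
    """Planted vertex-disjoint disease pairs (comorbid co-occurrence)."""
    return [
        AssociationSpec("I10", "I63", 3.0),
        AssociationSpec("E11", "E78", 3.5),
        AssociationSpec("J44", "I50", 3.0),
        AssociationSpec("I25", "I70", 3.0),
        AssociationSpec("M47", "M81", 2.5),
    ]


def default_config(n_patients: int = 5000, seed: int = 0,
                   contamination: ContaminationRates | None = None,
                   ) -> SimulationConfig:
    """Study-condition defaults: subgroup mix and prevalences as observed in
    large CRC discharge cohorts, ~2.5 look-back admissions per patient."""
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        disease_panel=default_panel(),
        association_spec=default_associations(),
        contamination=contamination or ContaminationRates(),
    )
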