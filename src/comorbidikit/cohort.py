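"""Index hospitalizations, inclusion/exclusion rules, covariates, outcomes.

The study cohort is one entry per patient: the earliest admission in the
study window (calendar year 2002 by default) whose principal diagnosis
matches the disease's ICD-9-CM prefix family. Patients younger than 18 at
the index admission, or not discharged by the study cutoff, are excluded and
counted in a per-rule exclusion ledger.

Baseline covariates are age (completed years at index admission), sex, the
aborigine indicator, and surgery (index DRG in the surgical-DRG set). The
two outcomes are in-hospital death (death date within the closed
[admit, discharge] interval, or the claim's discharge_alive=False flag) and
death within a closed 365-day window anchored at the index admit date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional

import pandas as pd

from .comorbidity import load_surgical_drgs
from .errors import ConfigError, DataInconsistencyError
from .io import AdmissionRecord, ClaimsDataset, PatientRecord, normalize_icd9

__all__ = [
    "DiseaseDefinition",
    "DISEASES",
    "CohortEntry",
    "STUDY_WINDOW",
    "find_index_admissions",
    "apply_exclusions",
    "derive_outcomes",
    "build_cohort",
    "cohort_frame",
]

STUDY_WINDOW = (date(2002, 1, 1), date(2002, 12, 31))


@dataclass(frozen=True)
class DiseaseDefinition:
    """A study disease as a family of ICD-9-CM principal-diagnosis prefixes."""

    name: str
    icd9_prefixes: tuple[str, ...]

    def __post_init__(self):
        if not self.icd9_prefixes:
            raise ConfigError(f"disease {self.name!r} has no ICD-9 prefixes")
        object.__setattr__(
            self, "icd9_prefixes",
            tuple(normalize_icd9(p) for p in self.icd9_prefixes))

    def matches(self, code: str) -> bool:
        c = normalize_icd9(code)
        return any(c.startswith(p) for p in self.icd9_prefixes)


DISEASES = {
    "AMI": DiseaseDefinition("AMI", ("410",)),
    "COPD": DiseaseDefinition("COPD", ("490", "491", "492", "494", "496")),
}


@dataclass(frozen=True)
class CohortEntry:
    """A retained patient's index admission with covariates and outcomes."""

    patient_id: str
    index_admission: AdmissionRecord
    age_years: int
    sex: str
    aborigine: bool
    surgery: bool
    died_in_hospital: bool
    died_within_1yr: bool


def completed_years(birth: date, at: date) -> int:
    """Age in completed calendar years."""
    return at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))


def find_index_admissions(dataset: ClaimsDataset,
                          disease: DiseaseDefinition,
                          window: tuple[date, date] = STUDY_WINDOW,
                          ) -> dict[str, AdmissionRecord]:
    """Earliest qualifying admission per patient within the study window.

    Ties on admit_date are broken by longer stay, then lexicographically
    smallest principal diagnosis (deterministic; same-day transfers and
    re-admissions are otherwise treated as distinct admissions).
    """
    lo, hi = window
    if lo > hi:
        raise ConfigError(f"invalid study window {window}")
    best: dict[str, AdmissionRecord] = {}
    for adm in dataset.admissions:
        if not (lo <= adm.admit_date <= hi):
            continue
        if not disease.matches(adm.principal_dx):
            continue
        cur = best.get(adm.patient_id)
        if cur is None:
            best[adm.patient_id] = adm
            continue
        key = (adm.admit_date, -adm.length_of_stay, normalize_icd9(adm.principal_dx))
        cur_key = (cur.admit_date, -cur.length_of_stay,
                   normalize_icd9(cur.principal_dx))
        if key < cur_key:
            best[adm.patient_id] = adm
    return best


def apply_exclusions(candidates: dict[str, AdmissionRecord],
                     patients: Iterable[PatientRecord],
                     cutoff: date = STUDY_WINDOW[1],
                     min_age: int = 18,
                     ) -> tuple[dict[str, AdmissionRecord], dict[str, int]]:
    """Drop under-age patients and stays not discharged by the cutoff.

    Age is completed years at the index admit date; age exactly ``min_age``
    is retained ("younger than 18" is excluded). Returns the survivors plus
    an exclusion ledger with per-rule counts.
    """
    index = {p.patient_id: p for p in patients}
    ledger = {"age<18": 0, "not_discharged_by_cutoff": 0}
    kept: dict[str, AdmissionRecord] = {}
    for pid, adm in candidates.items():
        pat = index[pid]
        if completed_years(pat.birth_date, adm.admit_date) < min_age:
            ledger["age<18"] += 1
            continue
        if adm.discharge_date > cutoff:
            ledger["not_discharged_by_cutoff"] += 1
            continue
        kept[pid] = adm
    return kept, ledger


def derive_outcomes(candidates: dict[str, AdmissionRecord],
                    patients: Iterable[PatientRecord],
                    surgical_drgs: Optional[frozenset[str]] = None,
                    followup_days: int = 365,
                    ) -> list[CohortEntry]:
    """Attach covariates and both mortality outcomes to retained patients.

    In-hospital death: death date within the closed [admit, discharge]
    interval, or the claim's discharge_alive flag is False; when the two
    signals disagree a conflict warning is emitted (both sources are kept —
    either one asserts the death). 1-year death: death date within the
    closed window [admit, admit + followup_days]. A death date earlier than
    the index admit date is a data inconsistency.
    """
    if surgical_drgs is None:
        surgical_drgs = load_surgical_drgs()
    index = {p.patient_id: p for p in patients}
    entries: list[CohortEntry] = []
    for pid in candidates:
        adm = candidates[pid]
        pat = index[pid]
        death = pat.death_date
        if death is not None and death < adm.admit_date:
            raise DataInconsistencyError(
                f"patient {pid!r}: death date {death} precedes index "
                f"admission {adm.admit_date}")
        inferred_in_hosp = (death is not None
                            and adm.admit_date <= death <= adm.discharge_date)
        claim_died = not adm.discharge_alive
        if inferred_in_hosp != claim_died:
            warnings.warn(
                f"patient {pid!r}: claims discharge_alive="
                f"{adm.discharge_alive} conflicts with death registry "
                f"(death_date={death}); counting the admission as an "
                f"in-hospital death")
        died_in_hospital = inferred_in_hosp or claim_died
        died_within_1yr = (death is not None and
                           death <= adm.admit_date + timedelta(days=followup_days))
        entries.append(CohortEntry(
            patient_id=pid,
            index_admission=adm,
            age_years=completed_years(pat.birth_date, adm.admit_date),
            sex=pat.sex,
            aborigine=pat.aborigine,
            surgery=adm.drg in surgical_drgs,
            died_in_hospital=died_in_hospital,
            died_within_1yr=died_within_1yr,
        ))
    return entries


def build_cohort(dataset: ClaimsDataset,
                 disease: DiseaseDefinition | str,
                 window: tuple[date, date] = STUDY_WINDOW,
                 surgical_drgs: Optional[frozenset[str]] = None,
                 ) -> tuple[list[CohortEntry], dict[str, int]]:
    """Full cohort construction: index selection, exclusions, outcomes."""
    if isinstance(disease, str):
        try:
            disease = DISEASES[disease]
        except KeyError:
            raise ConfigError(
                f"unknown disease {disease!r}; expected one of "
                f"{sorted(DISEASES)}") from None
    candidates = find_index_admissions(dataset, disease, window)
    kept, ledger = apply_exclusions(candidates, dataset.patients,
                                    cutoff=window[1])
    entries = derive_outcomes(kept, dataset.patients, surgical_drgs)
    return entries, ledger


def cohort_frame(cohort: Iterable[CohortEntry]) -> pd.DataFrame:
    """Cohort as a tidy DataFrame (one row per entry)."""
    rows = [{
        "patient_id": e.patient_id,
        "admit_date": e.index_admission.admit_date.isoformat(),
        "discharge_date": e.index_admission.discharge_date.isoformat(),
        "principal_dx": e.index_admission.principal_dx,
        "drg": e.index_admission.drg,
        "age_years": e.age_years,
        "male": int(e.sex == "male"),
        "aborigine": int(e.aborigine),
        "surgery": int(e.surgery),
        "died_in_hospital": int(e.died_in_hospital),
        "died_within_1yr": int(e.died_within_1yr),
    } for e in cohort]
    return pd.DataFrame(rows, columns=[
        "patient_id", "admit_date", "discharge_date", "principal_dx", "drg",
        "age_years", "male", "aborigine", "surgery", "died_in_hospital",
        "died_within_1yr"])
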