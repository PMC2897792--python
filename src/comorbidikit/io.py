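"""Canonical data model for inpatient claims and delimited-file round trips.

The unit of observation is one hospitalization claim: admission/discharge
dates, a principal ICD-9-CM diagnosis, up to four secondary diagnoses, up to
three procedure codes, and a DRG. Demographics (birth date, sex, an
aborigine indicator for the race covariate) and an optional death date come
from a separate patients table, linked by an opaque patient id.

Files are plain CSV with ISO-8601 dates; all interval logic elsewhere in the
package treats calendar-day intervals as closed. ICD-9-CM codes are stored
as given and compared on their decimal-free canonical form
(:func:`normalize_icd9`) with prefix semantics ("410" matches "41071").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import LinkageError, ValidationError

__all__ = [
    "AdmissionRecord",
    "PatientRecord",
    "ClaimsDataset",
    "normalize_icd9",
    "read_claims",
    "write_claims",
    "ADMISSION_COLUMNS",
    "PATIENT_COLUMNS",
]

_ICD9_CHARS = frozenset("0123456789VE.")

ADMISSION_COLUMNS = [
    "patient_id", "admit_date", "discharge_date", "principal_dx",
    "dx1", "dx2", "dx3", "dx4", "proc1", "proc2", "proc3",
    "drg", "discharge_alive",
]
PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "aborigine", "death_date"]


def normalize_icd9(code: str) -> str:
    """Return the decimal-free canonical form of an ICD-9-CM code.

    "410.71" and "41071" normalize identically; V and E codes keep their
    letter prefix. Idempotent. Raises :class:`ValidationError` for empty
    input or characters outside ``[0-9VE.]``.
    """
    if code is None:
        raise ValidationError("ICD-9-CM code is missing")
    c = str(code).strip().upper()
    if not c:
        raise ValidationError("ICD-9-CM code is empty")
    bad = set(c) - _ICD9_CHARS
    if bad:
        raise ValidationError(
            f"ICD-9-CM code {code!r} contains invalid characters {sorted(bad)}"
        )
    c = c.replace(".", "")
    if not c:
        raise ValidationError(f"ICD-9-CM code {code!r} has no digits")
    return c


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization claim.

    Invariants: admit_date <= discharge_date, at most 4 secondary diagnoses
    and 3 procedures, non-empty principal diagnosis.
    """

    patient_id: str
    admit_date: date
    discharge_date: date
    principal_dx: str
    secondary_dx: tuple[str, ...] = ()
    procedures: tuple[str, ...] = ()
    drg: str = ""
    discharge_alive: bool = True

    def __post_init__(self):
        object.__setattr__(self, "secondary_dx", tuple(self.secondary_dx))
        object.__setattr__(self, "procedures", tuple(self.procedures))
        if self.admit_date > self.discharge_date:
            raise ValidationError(
                f"admission for {self.patient_id!r}: admit_date "
                f"{self.admit_date} after discharge_date {self.discharge_date}"
            )
        if len(self.secondary_dx) > 4:
            raise ValidationError(
                f"admission for {self.patient_id!r}: "
                f"{len(self.secondary_dx)} secondary diagnoses (at most 4)"
            )
        if len(self.procedures) > 3:
            raise ValidationError(
                f"admission for {self.patient_id!r}: "
                f"{len(self.procedures)} procedures (at most 3)"
            )
        normalize_icd9(self.principal_dx)  # raises if empty/invalid
        for c in self.secondary_dx:
            normalize_icd9(c)

    @property
    def length_of_stay(self) -> int:
        return (self.discharge_date - self.admit_date).days


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus an optional death-registry date."""

    patient_id: str
    birth_date: date
    sex: str
    aborigine: bool = False
    death_date: Optional[date] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id!r}: sex must be male/female, "
                f"got {self.sex!r}"
            )
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ValidationError(
                f"patient {self.patient_id!r}: death_date {self.death_date} "
                f"before birth_date {self.birth_date}"
            )


@dataclass
class ClaimsDataset:
    """Linked admissions + patients; every admission resolves to a patient."""

    admissions: list[AdmissionRecord] = field(default_factory=list)
    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")
        self._patient_index = {p.patient_id: p for p in self.patients}
        orphans = {a.patient_id for a in self.admissions} - set(ids)
        if orphans:
            raise LinkageError(
                f"admissions reference {len(orphans)} patient id(s) with no "
                f"demographics record: {sorted(orphans)}",
                orphan_ids=orphans,
            )
        # resubmitted claims: drop rows identical on every field, with a warning
        seen, deduped = set(), []
        for a in self.admissions:
            key = (a.patient_id, a.admit_date, a.discharge_date, a.principal_dx,
                   a.secondary_dx, a.procedures, a.drg, a.discharge_alive)
            if key in seen:
                warnings.warn(
                    f"dropping fully duplicate admission row for "
                    f"{a.patient_id!r} admitted {a.admit_date}"
                )
                continue
            seen.add(key)
            deduped.append(a)
        self.admissions = deduped
        short = [(a.patient_id, a.admit_date, a.discharge_date, a.principal_dx)
                 for a in self.admissions]
        if len(set(short)) != len(short):
            raise ValidationError(
                "admissions duplicated on (patient_id, admit_date, "
                "discharge_date, principal_dx) but differing elsewhere"
            )

    def patient(self, patient_id: str) -> PatientRecord:
        return self._patient_index[patient_id]

    def admissions_of(self, patient_id: str) -> list[AdmissionRecord]:
        return [a for a in self.admissions if a.patient_id == patient_id]

    def admissions_by_patient(self) -> dict[str, list[AdmissionRecord]]:
        out: dict[str, list[AdmissionRecord]] = {p.patient_id: [] for p in self.patients}
        for a in self.admissions:
            out[a.patient_id].append(a)
        return out


def _parse_date(value: str, where: str, diagnostics: list) -> Optional[date]:
    try:
        return date.fromisoformat(value)
    except ValueError:
        diagnostics.append(f"{where}: unparseable date {value!r}")
        return None


def _parse_bool(value: str, where: str, diagnostics: list) -> Optional[bool]:
    v = str(value).strip().lower()
    if v in ("true", "t", "1", "yes"):
        return True
    if v in ("false", "f", "0", "no"):
        return False
    diagnostics.append(f"{where}: unparseable boolean {value!r}")
    return None


def read_claims(admissions_path, patients_path) -> ClaimsDataset:
    """Read and validate the admissions/patients CSV pair.

    Every malformed row produces a located diagnostic; if any row fails, a
    single :class:`ValidationError` carrying all diagnostics is raised. A
    missing file raises ``FileNotFoundError``.
    """
    admissions_path, patients_path = Path(admissions_path), Path(patients_path)
    for p in (admissions_path, patients_path):
        if not p.exists():
            raise FileNotFoundError(p)

    adm_df = pd.read_csv(admissions_path, dtype=str, keep_default_na=False)
    pat_df = pd.read_csv(patients_path, dtype=str, keep_default_na=False)

    diagnostics: list[str] = []
    extra = [c for c in adm_df.columns if c not in ADMISSION_COLUMNS]
    if extra:
        raise ValidationError(
            f"{admissions_path.name}: unexpected columns {extra} — the schema "
            f"allows at most 4 secondary diagnoses (dx1..dx4) and 3 "
            f"procedures (proc1..proc3)"
        )
    missing = [c for c in ADMISSION_COLUMNS if c not in adm_df.columns]
    if missing:
        raise ValidationError(f"{admissions_path.name}: missing columns {missing}")
    missing = [c for c in PATIENT_COLUMNS if c not in pat_df.columns]
    if missing:
        raise ValidationError(f"{patients_path.name}: missing columns {missing}")

    patients: list[PatientRecord] = []
    for i, row in enumerate(pat_df.itertuples(index=False), start=2):
        where = f"{patients_path.name}:{i}"
        birth = _parse_date(row.birth_date, where, diagnostics)
        dd = row.death_date.strip()
        death = _parse_date(dd, where, diagnostics) if dd else None
        ab = _parse_bool(row.aborigine, where, diagnostics)
        if birth is None or ab is None or (dd and death is None):
            continue
        try:
            patients.append(PatientRecord(
                patient_id=row.patient_id, birth_date=birth, sex=row.sex,
                aborigine=ab, death_date=death))
        except ValidationError as e:
            diagnostics.append(f"{where}: {e}")

    admissions: list[AdmissionRecord] = []
    for i, row in enumerate(adm_df.itertuples(index=False), start=2):
        where = f"{admissions_path.name}:{i}"
        admit = _parse_date(row.admit_date, where, diagnostics)
        disch = _parse_date(row.discharge_date, where, diagnostics)
        alive = _parse_bool(row.discharge_alive, where, diagnostics)
        if admit is None or disch is None or alive is None:
            continue
        secondary = tuple(v for v in (row.dx1, row.dx2, row.dx3, row.dx4)
                          if v.strip())
        procs = tuple(v for v in (row.proc1, row.proc2, row.proc3) if v.strip())
        try:
            admissions.append(AdmissionRecord(
                patient_id=row.patient_id, admit_date=admit,
                discharge_date=disch, principal_dx=row.principal_dx,
                secondary_dx=secondary, procedures=procs, drg=row.drg,
                discharge_alive=alive))
        except ValidationError as e:
            diagnostics.append(f"{where}: {e}")

    if diagnostics:
        raise ValidationError(
            f"{len(diagnostics)} invalid row(s) in claims input",
            diagnostics=diagnostics,
        )
    return ClaimsDataset(admissions=admissions, patients=patients)


def write_claims(dataset: ClaimsDataset, out_dir) -> tuple[Path, Path]:
    """Write the CSV pair so that ``read_claims`` reproduces the dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adm_rows = []
    for a in dataset.admissions:
        dx = list(a.secondary_dx) + [""] * (4 - len(a.secondary_dx))
        pr = list(a.procedures) + [""] * (3 - len(a.procedures))
        adm_rows.append({
            "patient_id": a.patient_id,
            "admit_date": a.admit_date.isoformat(),
            "discharge_date": a.discharge_date.isoformat(),
            "principal_dx": a.principal_dx,
            "dx1": dx[0], "dx2": dx[1], "dx3": dx[2], "dx4": dx[3],
            "proc1": pr[0], "proc2": pr[1], "proc3": pr[2],
            "drg": a.drg,
            "discharge_alive": str(a.discharge_alive).lower(),
        })
    pat_rows = [{
        "patient_id": p.patient_id,
        "birth_date": p.birth_date.isoformat(),
        "sex": p.sex,
        "aborigine": str(p.aborigine).lower(),
        "death_date": p.death_date.isoformat() if p.death_date else "",
    } for p in dataset.patients]

    adm_path = out_dir / "admissions.csv"
    pat_path = out_dir / "patients.csv"
    pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS).to_csv(adm_path, index=False)
    pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS).to_csv(pat_path, index=False)
    return adm_path, pat_path
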