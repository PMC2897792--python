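"""The three claims-based comorbidity measures as binary-category mappers.

Three ICD-9-CM classifiers are supported, each turning a patient's eligible
diagnosis codes into presence/absence flags (no weighted score):

* ``charlson_deyo`` — the Deyo adaptation of the Charlson index,
  17 categories;
* ``charlson_romano`` — the Romano (Dartmouth–Manitoba) adaptation,
  17 categories with broader code lists;
* ``elixhauser`` — the 30-category Elixhauser measure, which additionally
  screens index-admission codes against a DRG-relatedness table so that
  conditions plausibly arising from the index stay are not counted as
  comorbidities.

Two data periods govern which codes are eligible: the index hospitalization
only (its secondary diagnoses), or the index plus all hospitalizations in a
1-year lookback window before the index admission (their principal and
secondary diagnoses). The index admission's principal diagnosis never
contributes: it defines the cohort condition.

Reference code lists ship as TSV snapshots under ``comorbidikit/data``; the
DRG screen and the surgical-DRG list are synthetic stand-ins (the mapping
used with Taiwan's DRG version is not public) and both are user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from importlib import resources
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .errors import ConfigError, ReferenceDataError
from .io import AdmissionRecord, ClaimsDataset, normalize_icd9

__all__ = [
    "METHOD_NAMES",
    "ComorbidityMethod",
    "DataPeriod",
    "INDEX_ONLY",
    "INDEX_PLUS_PRIOR",
    "ComorbidityProfile",
    "EligibleCode",
    "load_method",
    "load_surgical_drgs",
    "eligible_diagnoses",
    "map_profile",
    "profile_matrix",
]

METHOD_NAMES = ("charlson_deyo", "charlson_romano", "elixhauser")
_EXPECTED_N_CATEGORIES = {"charlson_deyo": 17, "charlson_romano": 17,
                          "elixhauser": 30}


@dataclass(frozen=True)
class DataPeriod:
    """Which admissions contribute comorbidity evidence.

    ``index_only`` uses the index admission's secondary diagnoses;
    ``index_plus_prior`` adds every diagnosis field of admissions admitted
    within ``lookback_days`` (exactly 365) before the index admission.
    """

    kind: str
    lookback_days: int = 365

    def __post_init__(self):
        if self.kind not in ("index_only", "index_plus_prior"):
            raise ConfigError(f"unknown data period kind {self.kind!r}")
        if self.kind == "index_plus_prior" and self.lookback_days != 365:
            raise ConfigError("index_plus_prior uses a 1-year (365-day) lookback")


INDEX_ONLY = DataPeriod("index_only")
INDEX_PLUS_PRIOR = DataPeriod("index_plus_prior")


class EligibleCode(NamedTuple):
    code: str          # canonical decimal-free form
    source: str        # "index" | "prior"
    position: str      # "principal" | "secondary"


@dataclass
class ComorbidityMethod:
    """One measure: category list, code map, optional DRG screen, hierarchy."""

    name: str
    categories: list[str]
    code_map: dict[str, list[str]]             # category -> ICD-9 prefixes
    drg_screen: Optional[dict[str, frozenset[str]]] = None
    prior_only_categories: frozenset[str] = frozenset()
    hierarchy_rules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        known = set(self.categories)
        for dom, sup in self.hierarchy_rules:
            if dom not in known or sup not in known:
                raise ReferenceDataError(
                    f"{self.name}: hierarchy rule ({dom}, {sup}) references "
                    f"an unknown category")
        unknown = self.prior_only_categories - known
        if unknown:
            raise ConfigError(
                f"{self.name}: prior_only categories {sorted(unknown)} unknown")
        # prefix -> categories lookup; a code matches by any of its own prefixes
        idx: dict[str, set[str]] = {}
        for cat, prefixes in self.code_map.items():
            for p in prefixes:
                idx.setdefault(p, set()).add(cat)
        self._prefix_index = idx

    def matching_categories(self, code: str) -> set[str]:
        """Categories whose prefix list matches the canonical ``code``."""
        out: set[str] = set()
        for length in range(1, len(code) + 1):
            hit = self._prefix_index.get(code[:length])
            if hit:
                out |= hit
        return out


@dataclass(frozen=True)
class ComorbidityProfile:
    """Per-patient flags for one method under one data period.

    Hierarchy rules are already applied; the flag-key set equals the
    method's category list exactly.
    """

    patient_id: str
    method: str
    period: str
    flags: dict[str, bool]


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("comorbidikit.data") / name
    with resources.as_file(ref) as path:
        try:
            return pd.read_csv(path, sep="\t", dtype=str)
        except Exception as e:  # malformed table
            raise ReferenceDataError(f"{name}: {e}") from e


def load_method(name: str,
                codes_table: Optional[pd.DataFrame] = None,
                drg_screen_table: Optional[pd.DataFrame] = None,
                hierarchy_table: Optional[pd.DataFrame] = None,
                prior_only: str | Iterable[str] = "none") -> ComorbidityMethod:
    """Build a :class:`ComorbidityMethod` from the bundled reference tables.

    Parameters
    ----------
    name
        ``charlson_deyo``, ``charlson_romano`` or ``elixhauser``.
    codes_table, drg_screen_table, hierarchy_table
        Optional replacement tables with the packaged column layouts
        (``method/category/icd9_prefix``, ``category/drg``,
        ``method/dominant/suppressed``).
    prior_only
        For the Charlson variants: ``"none"`` (default — every category is
        countable from index secondary diagnoses), ``"complication_prone"``
        (the shipped alternative list of categories countable only from
        prior admissions), or an explicit iterable of category names.
    """
    if name not in METHOD_NAMES:
        raise ConfigError(
            f"unknown comorbidity method {name!r}; expected one of {METHOD_NAMES}")

    codes = codes_table if codes_table is not None else _read_packaged_tsv(
        "comorbidity_codes.tsv")
    for col in ("method", "category", "icd9_prefix"):
        if col not in codes.columns:
            raise ReferenceDataError(f"codes table lacks column {col!r}")
    sub = codes[codes["method"] == name]
    if sub.empty:
        raise ReferenceDataError(f"no code rows for method {name!r}")
    categories = list(dict.fromkeys(sub["category"]))
    expected = _EXPECTED_N_CATEGORIES[name]
    if len(categories) != expected:
        raise ReferenceDataError(
            f"{name}: reference table defines {len(categories)} categories, "
            f"expected {expected}")
    code_map = {
        cat: [normalize_icd9(p) for p in sub.loc[sub["category"] == cat,
                                                 "icd9_prefix"]]
        for cat in categories
    }

    screen = None
    if name == "elixhauser":
        st = drg_screen_table if drg_screen_table is not None else \
            _read_packaged_tsv("elixhauser_drg_screen_synthetic.tsv")
        for col in ("category", "drg"):
            if col not in st.columns:
                raise ReferenceDataError(f"DRG screen table lacks column {col!r}")
        screen = {cat: frozenset(g["drg"]) for cat, g in st.groupby("category")}
        unknown = set(screen) - set(categories)
        if unknown:
            raise ReferenceDataError(
                f"DRG screen references unknown categories {sorted(unknown)}")

    ht = hierarchy_table if hierarchy_table is not None else \
        _read_packaged_tsv("hierarchy.tsv")
    hsub = ht[ht["method"] == name]
    rules = list(zip(hsub["dominant"], hsub["suppressed"]))

    if name == "elixhauser":
        prior_set: frozenset[str] = frozenset()
    elif prior_only == "none":
        prior_set = frozenset()
    elif prior_only == "complication_prone":
        alt = _read_packaged_tsv("charlson_prior_only_alternative.tsv")
        prior_set = frozenset(alt.loc[alt["method"] == name, "category"])
    else:
        prior_set = frozenset(prior_only)

    return ComorbidityMethod(
        name=name, categories=categories, code_map=code_map,
        drg_screen=screen, prior_only_categories=prior_set,
        hierarchy_rules=rules)


def load_surgical_drgs(table: Optional[pd.DataFrame] = None) -> frozenset[str]:
    """The DRG codes counted as surgical (synthetic stand-in list by default)."""
    t = table if table is not None else _read_packaged_tsv(
        "surgical_drgs_synthetic.tsv")
    if "drg" not in t.columns:
        raise ReferenceDataError("surgical DRG table lacks column 'drg'")
    return frozenset(t["drg"])


def eligible_diagnoses(admissions: Iterable[AdmissionRecord],
                       index: AdmissionRecord,
                       period: DataPeriod,
                       method: Optional[ComorbidityMethod] = None,
                       ) -> list[EligibleCode]:
    """Diagnosis codes eligible to set comorbidity flags for one patient.

    The index principal diagnosis is never eligible. Under
    ``index_plus_prior``, admissions with admit_date in
    ``[index.admit_date - 365 d, index.admit_date)`` contribute their
    principal and secondary diagnoses, tagged ``source="prior"``. The
    ``method`` argument is accepted for interface symmetry; eligibility does
    not depend on it.
    """
    out = [EligibleCode(normalize_icd9(c), "index", "secondary")
           for c in index.secondary_dx]
    if period.kind == "index_plus_prior":
        lo = index.admit_date - timedelta(days=period.lookback_days)
        for adm in admissions:
            if adm is index:
                continue
            if lo <= adm.admit_date < index.admit_date:
                out.append(EligibleCode(normalize_icd9(adm.principal_dx),
                                        "prior", "principal"))
                out.extend(EligibleCode(normalize_icd9(c), "prior", "secondary")
                           for c in adm.secondary_dx)
    return out


def map_profile(eligible: Iterable[EligibleCode],
                index_drg: str,
                method: ComorbidityMethod,
                period: DataPeriod,
                patient_id: str = "") -> ComorbidityProfile:
    """Apply one method's rules to a patient's eligible codes.

    A category is flagged iff some eligible code prefix-matches its code
    list, subject to:

    * Elixhauser DRG screen — an index-sourced code cannot set a category
      whose screen set contains the index DRG (prior-sourced codes bypass
      the screen: a condition documented before the index stay cannot be a
      complication of it);
    * Charlson prior-admission rule — a category in
      ``prior_only_categories`` needs at least one matching prior-sourced
      code.

    Hierarchy rules then clear a suppressed category whenever its dominant
    partner is set (e.g. complicated diabetes suppresses uncomplicated).
    """
    flags = {cat: False for cat in method.categories}
    for ec in eligible:
        for cat in method.matching_categories(ec.code):
            if ec.source == "index":
                if method.drg_screen is not None and \
                        index_drg in method.drg_screen.get(cat, frozenset()):
                    continue
                if cat in method.prior_only_categories:
                    continue
            flags[cat] = True
    for dominant, suppressed in method.hierarchy_rules:
        if flags[dominant]:
            flags[suppressed] = False
    return ComorbidityProfile(patient_id=patient_id, method=method.name,
                              period=period.kind, flags=flags)


def profile_matrix(cohort, dataset: ClaimsDataset,
                   method: ComorbidityMethod,
                   period: DataPeriod) -> pd.DataFrame:
    """Patients × categories binary table (one row per cohort entry).

    Column order is the method's category order; the index is patient_id in
    cohort order.
    """
    by_patient = dataset.admissions_by_patient()
    rows, ids = [], []
    for entry in cohort:
        codes = eligible_diagnoses(by_patient[entry.patient_id],
                                   entry.index_admission, period, method)
        prof = map_profile(codes, entry.index_admission.drg, method, period,
                           patient_id=entry.patient_id)
        rows.append([int(prof.flags[c]) for c in method.categories])
        ids.append(entry.patient_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"),
                        columns=method.categories, dtype="int8")
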