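"""Synthetic inpatient claims with a known logistic mortality model.

The generator emulates the statistical structure the downstream analysis
assumes, for a single-payer claims extract:

* demographics drawn from configured marginals (age ~ Normal, truncated to
  [18, 100]; sex, aborigine and surgery as Bernoulli fractions);
* latent comorbidities drawn independently per category with configured
  prevalences;
* an index admission in 2002 with a principal diagnosis from the disease's
  code family and a DRG from a disease-to-DRG table (surgical DRG iff the
  patient receives surgery);
* Poisson-distributed prior admissions in the 1-year lookback window;
* claims coding noise: on any given admission a latent comorbidity is coded
  as a secondary diagnosis only with probability ``carryover_prob`` (at most
  4 slots per claim), which is exactly the mechanism that makes lookback
  periods informative;
* death drawn from a logistic model over the latent flags and baseline
  covariates, with two intercepts (in-hospital and 1-year) sharing one
  coefficient vector. One uniform draw per patient decides both outcomes,
  so in-hospital death implies 1-year death and common random numbers make
  mortality monotone in any coefficient.

The age coefficient is log-odds per year applied to (age − 70); comorbidity
and indicator coefficients are plain log-odds. Ground truth (latent flags,
realized probabilities, generating coefficients) is exported for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigError
from .io import AdmissionRecord, ClaimsDataset, PatientRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_population",
    "table1_summary",
    "calibrate_intercept",
    "load_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("ami", "copd", "dominance")

BASELINE_COVARIATES = ("age", "male", "aborigine", "surgery")

# Disease-specific code/DRG pools (DRGs refer to the synthetic stand-in
# tables bundled with the mappers; surgical pools are subsets of the
# synthetic surgical-DRG list).
DISEASE_DEFAULTS = {
    "AMI": {
        "index_dx_pool": ["41001", "41041", "41071", "41091"],
        "drg_medical": ["121", "122", "123"],
        "drg_surgical": ["106", "107", "112"],
    },
    "COPD": {
        "index_dx_pool": ["4910", "49121", "4928", "496"],
        "drg_medical": ["088"],
        "drg_surgical": ["075", "076", "077"],
    },
}

GENERIC_PRINCIPAL_POOL = ["78609", "7802", "486", "5990"]
GENERIC_PRIOR_DRG = "182"


@dataclass
class SimulationConfig:
    """Scenario parameters; maps one-to-one onto the scenario YAML files."""

    n_patients: int
    disease: str
    age_mean_sd: tuple[float, float]
    male_frac: float
    aborigine_frac: float
    surgery_frac: float
    comorbidity_prevalences: dict[str, float]
    comorbidity_codes: dict[str, list[str]]
    mortality_coefficients: dict[str, float]
    mortality_intercepts: tuple[float, float]  # (in-hospital, 1-year)
    prior_admission_rate: float = 1.0
    carryover_prob: float = 1.0
    seed: int = 0
    prior_principal_comorbidity_prob: float = 0.7
    index_dx_pool: Optional[list[str]] = None
    drg_medical: Optional[list[str]] = None
    drg_surgical: Optional[list[str]] = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.disease not in DISEASE_DEFAULTS:
            raise ConfigError(
                f"unknown disease {self.disease!r}; expected one of "
                f"{sorted(DISEASE_DEFAULTS)}")
        probs = {"male_frac": self.male_frac,
                 "aborigine_frac": self.aborigine_frac,
                 "surgery_frac": self.surgery_frac,
                 "carryover_prob": self.carryover_prob,
                 "prior_principal_comorbidity_prob":
                     self.prior_principal_comorbidity_prob,
                 **{f"prevalence[{k}]": v
                    for k, v in self.comorbidity_prevalences.items()}}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} is not a probability")
        if self.prior_admission_rate < 0:
            raise ConfigError("prior_admission_rate must be >= 0")
        valid_keys = set(BASELINE_COVARIATES) | set(self.comorbidity_prevalences)
        unknown = set(self.mortality_coefficients) - valid_keys
        if unknown:
            raise ConfigError(
                f"mortality_coefficients reference unknown names "
                f"{sorted(unknown)}; allowed: baseline covariates "
                f"{BASELINE_COVARIATES} and configured comorbidity categories")
        missing = set(self.comorbidity_prevalences) - set(self.comorbidity_codes)
        if missing:
            raise ConfigError(
                f"no ICD-9 code pool configured for categories {sorted(missing)}")
        for cat, pool in self.comorbidity_codes.items():
            if not pool:
                raise ConfigError(f"empty code pool for category {cat!r}")
        defaults = DISEASE_DEFAULTS[self.disease]
        if self.index_dx_pool is None:
            self.index_dx_pool = list(defaults["index_dx_pool"])
        if self.drg_medical is None:
            self.drg_medical = list(defaults["drg_medical"])
        if self.drg_surgical is None:
            self.drg_surgical = list(defaults["drg_surgical"])
        self.age_mean_sd = (float(self.age_mean_sd[0]), float(self.age_mean_sd[1]))
        self.mortality_intercepts = (float(self.mortality_intercepts[0]),
                                     float(self.mortality_intercepts[1]))

    @property
    def categories(self) -> list[str]:
        return list(self.comorbidity_prevalences)

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None,
                  n_patients: Optional[int] = None) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, seed=seed, n_patients=n_patients)

    @classmethod
    def from_dict(cls, raw: dict, seed: Optional[int] = None,
                  n_patients: Optional[int] = None) -> "SimulationConfig":
        raw = dict(raw)
        if seed is not None:
            raw["seed"] = seed
        if n_patients is not None:
            raw["n_patients"] = n_patients
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown scenario keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e


@dataclass
class GroundTruth:
    """Latent flags, realized probabilities, and the generating model."""

    frame: pd.DataFrame
    coefficients: dict[str, float]
    intercepts: tuple[float, float]

    def design(self) -> pd.DataFrame:
        """Design matrix matching the generating parameterization.

        Columns: ``age`` as (age − 70) years, the three baseline indicators,
        then the latent category flags — so fitted slopes are directly
        comparable to :attr:`coefficients`.
        """
        cats = [c for c in self.frame.columns
                if c not in ("patient_id", "age_years", "male", "aborigine",
                             "surgery", "p_in_hospital", "p_one_year",
                             "died_in_hospital", "died_within_1yr")]
        X = pd.DataFrame({"age": self.frame["age_years"] - 70.0})
        for c in ("male", "aborigine", "surgery"):
            X[c] = self.frame[c].to_numpy()
        for c in cats:
            X[c] = self.frame[c].to_numpy()
        return X


def _birth_date(admit: date, age_years: int) -> date:
    # birthday placed ~30 days before the admission anniversary so completed
    # years at the admit date equal age_years exactly
    anchor = date(admit.year - age_years, admit.month, min(admit.day, 28))
    return anchor - timedelta(days=30)


def _linear_predictor(config: SimulationConfig, age: np.ndarray,
                      male: np.ndarray, aborigine: np.ndarray,
                      surgery: np.ndarray, latent: dict[str, np.ndarray],
                      ) -> np.ndarray:
    coefs = config.mortality_coefficients
    lp = np.zeros(len(age))
    lp += coefs.get("age", 0.0) * (age - 70.0)
    lp += coefs.get("male", 0.0) * male
    lp += coefs.get("aborigine", 0.0) * aborigine
    lp += coefs.get("surgery", 0.0) * surgery
    for cat, flags in latent.items():
        lp += coefs.get(cat, 0.0) * flags
    return lp


def simulate_population(config: SimulationConfig,
                        ) -> tuple[ClaimsDataset, GroundTruth]:
    """Generate one synthetic population; deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cats = config.categories

    # -- latent structure and outcomes (all vectorized, fixed draw order so
    #    that coefficient changes only move the final threshold comparison)
    age = np.clip(np.round(rng.normal(*config.age_mean_sd, size=n)),
                  18, 100).astype(int)
    male = (rng.random(n) < config.male_frac).astype(int)
    aborigine = (rng.random(n) < config.aborigine_frac).astype(int)
    surgery = (rng.random(n) < config.surgery_frac).astype(int)
    latent = {c: (rng.random(n) < config.comorbidity_prevalences[c]).astype(int)
              for c in cats}
    u_death = rng.random(n)

    lp = _linear_predictor(config, age, male, aborigine, surgery, latent)
    a0, a1 = config.mortality_intercepts
    p_in = expit(a0 + lp)
    p_1yr = np.maximum(p_in, expit(a1 + lp))
    died_in = u_death < p_in
    died_1yr = u_death < p_1yr

    index_offset = rng.integers(0, 334, size=n)   # admit in Jan..Nov 2002
    index_los = 1 + rng.poisson(6, size=n)
    n_prior = rng.poisson(config.prior_admission_rate, size=n)

    year_start = date(2002, 1, 1)
    admissions: list[AdmissionRecord] = []
    patients: list[PatientRecord] = []
    gt_rows = []

    for i in range(n):
        pid = f"P{i:06d}"
        present = [c for c in cats if latent[c][i]]
        admit = year_start + timedelta(days=int(index_offset[i]))
        discharge = min(admit + timedelta(days=int(index_los[i])),
                        date(2002, 12, 31))
        los = (discharge - admit).days

        def coded_secondary(adm_rng=rng):
            chosen = [c for c in present
                      if adm_rng.random() < config.carryover_prob]
            codes = [str(adm_rng.choice(config.comorbidity_codes[c]))
                     for c in chosen]
            if len(codes) > 4:
                keep = adm_rng.choice(len(codes), size=4, replace=False)
                codes = [codes[k] for k in sorted(keep)]
            return tuple(codes)

        # prior admissions in the lookback year; one per calendar day so
        # records stay distinct on (patient, admit_date)
        used_offsets: set[int] = set()
        for _ in range(int(n_prior[i])):
            offset = int(rng.integers(1, 366))
            while offset in used_offsets:
                offset = int(rng.integers(1, 366))
            used_offsets.add(offset)
            p_admit = admit - timedelta(days=offset)
            p_los = 1 + int(rng.poisson(4))
            p_disch = min(p_admit + timedelta(days=p_los),
                          admit - timedelta(days=1))
            if present and rng.random() < config.prior_principal_comorbidity_prob:
                cat = present[int(rng.integers(0, len(present)))]
                principal = str(rng.choice(config.comorbidity_codes[cat]))
            else:
                principal = str(rng.choice(GENERIC_PRINCIPAL_POOL))
            admissions.append(AdmissionRecord(
                patient_id=pid, admit_date=p_admit, discharge_date=p_disch,
                principal_dx=principal, secondary_dx=coded_secondary(),
                procedures=(), drg=GENERIC_PRIOR_DRG, discharge_alive=True))

        # index admission
        principal = str(rng.choice(config.index_dx_pool))
        drg = str(rng.choice(config.drg_surgical if surgery[i]
                             else config.drg_medical))
        procedures = (f"36{int(rng.integers(10, 20))}",) if surgery[i] else ()
        admissions.append(AdmissionRecord(
            patient_id=pid, admit_date=admit, discharge_date=discharge,
            principal_dx=principal, secondary_dx=coded_secondary(),
            procedures=procedures, drg=drg,
            discharge_alive=not bool(died_in[i])))

        if died_in[i]:
            death: Optional[date] = admit + timedelta(days=int(rng.integers(0, los + 1)))
        elif died_1yr[i]:
            last = admit + timedelta(days=365)
            first = discharge + timedelta(days=1)
            span = max((last - first).days, 0)
            death = first + timedelta(days=int(rng.integers(0, span + 1)))
        else:
            death = None

        patients.append(PatientRecord(
            patient_id=pid, birth_date=_birth_date(admit, int(age[i])),
            sex="male" if male[i] else "female",
            aborigine=bool(aborigine[i]), death_date=death))

        gt_rows.append({
            "patient_id": pid, "age_years": int(age[i]),
            "male": int(male[i]), "aborigine": int(aborigine[i]),
            "surgery": int(surgery[i]),
            **{c: int(latent[c][i]) for c in cats},
            "p_in_hospital": float(p_in[i]), "p_one_year": float(p_1yr[i]),
            "died_in_hospital": int(died_in[i]),
            "died_within_1yr": int(died_1yr[i]),
        })

    dataset = ClaimsDataset(admissions=admissions, patients=patients)
    truth = GroundTruth(frame=pd.DataFrame(gt_rows),
                        coefficients=dict(config.mortality_coefficients),
                        intercepts=config.mortality_intercepts)
    return dataset, truth


def table1_summary(dataset: ClaimsDataset, cohort) -> pd.DataFrame:
    """Cohort characteristics: count/percent rows plus mean ± SD age."""
    cohort = list(cohort)
    n = len(cohort)
    if n == 0:
        import warnings
        warnings.warn("empty cohort: Table-1 summary is all zeros")
        ages = np.array([])
    else:
        ages = np.array([e.age_years for e in cohort], dtype=float)

    def count_row(label, pred):
        k = sum(1 for e in cohort if pred(e))
        return {"characteristic": label, "count": k,
                "percent": round(100.0 * k / n, 2) if n else 0.0}

    rows = [
        {"characteristic": "n", "count": n, "percent": 100.0 if n else 0.0},
        {"characteristic": "age_mean", "count": n,
         "percent": round(float(ages.mean()), 2) if n else 0.0},
        {"characteristic": "age_sd", "count": n,
         "percent": round(float(ages.std(ddof=0)), 2) if n else 0.0},
        count_row("male", lambda e: e.sex == "male"),
        count_row("aborigines", lambda e: e.aborigine),
        count_row("surgery", lambda e: e.surgery),
        count_row("in_hospital_mortality", lambda e: e.died_in_hospital),
        count_row("one_year_mortality", lambda e: e.died_within_1yr),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "count", "percent"])


def calibrate_intercept(target_rate: float, config: SimulationConfig,
                        n_draws: int = 200_000, seed: int = 12345) -> float:
    """Solve for the intercept giving a marginal event rate of ``target_rate``.

    Draws covariates and latent flags from the scenario's marginals and
    root-finds a on mean(expit(a + lp)) = target_rate. Used once when a
    scenario is authored; shipped scenarios store the solved value.
    """
    if not 0.0 < target_rate < 1.0:
        raise ConfigError("target_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = n_draws
    age = np.clip(np.round(rng.normal(*config.age_mean_sd, size=n)), 18, 100)
    male = (rng.random(n) < config.male_frac).astype(int)
    aborigine = (rng.random(n) < config.aborigine_frac).astype(int)
    surgery = (rng.random(n) < config.surgery_frac).astype(int)
    latent = {c: (rng.random(n) < p).astype(int)
              for c, p in config.comorbidity_prevalences.items()}
    lp = _linear_predictor(config, age, male, aborigine, surgery, latent)
    f = lambda a: float(np.mean(expit(a + lp))) - target_rate
    return float(brentq(f, -20.0, 20.0, xtol=1e-10))


def load_scenario(name_or_path, seed: Optional[int] = None,
                  n_patients: Optional[int] = None) -> SimulationConfig:
    """Load a packaged scenario by name ('ami', 'copd', 'dominance') or a
    YAML file path."""
    if isinstance(name_or_path, (str, Path)) and str(name_or_path) in SCENARIO_NAMES:
        ref = resources.files("comorbidikit.data") / "scenarios" / f"{name_or_path}.yaml"
        with resources.as_file(ref) as path:
            return SimulationConfig.from_yaml(path, seed=seed,
                                              n_patients=n_patients)
    if not Path(name_or_path).exists():
        raise ConfigError(
            f"scenario {name_or_path!r} is neither a packaged scenario "
            f"{SCENARIO_NAMES} nor an existing YAML file")
    return SimulationConfig.from_yaml(name_or_path, seed=seed,
                                      n_patients=n_patients)
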