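"""End-to-end orchestration: simulate/load → cohort → mapping → evaluation.

A run is described by a :class:`RunConfig` (usually a YAML file): either a
simulation scenario or a claims/patients CSV pair, plus the disease, the
comorbidity methods, the data periods, the outcomes, the bootstrap size and
a seed. ``run_pipeline`` executes every stage, writes all result tables to
the output directory, and leaves a JSON-lines audit trail (stage, seeds,
row counts, exclusion ledger).

All randomness is derived from the single run seed through
``numpy.random.SeedSequence`` spawning in a fixed order, so two runs with
identical config and seed produce byte-identical result CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import comorbidity as cm
from .cohort import build_cohort, cohort_frame
from .errors import ConfigError
from .evaluate import assemble_design, evaluate_model, paired_bootstrap_compare
from .io import read_claims, write_claims
from .simulate import load_scenario, simulate_population, table1_summary

__all__ = ["RunConfig", "run_pipeline"]

_PERIODS = {"index_only": cm.INDEX_ONLY, "index_plus_prior": cm.INDEX_PLUS_PRIOR}
_OUTCOME_COLS = {"in_hospital": "died_in_hospital", "one_year": "died_within_1yr"}


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: Path
    scenario: Optional[str] = None          # packaged name or YAML path
    admissions_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    disease: str = "AMI"
    methods: list[str] = field(default_factory=lambda: list(cm.METHOD_NAMES))
    periods: list[str] = field(
        default_factory=lambda: ["index_only", "index_plus_prior"])
    outcomes: list[str] = field(
        default_factory=lambda: ["in_hospital", "one_year"])
    n_bootstrap: int = 1000
    seed: int = 0
    n_patients: Optional[int] = None        # scenario override
    compare_methods: bool = True
    prior_only: str = "none"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not self.methods:
            raise ConfigError("at least one comorbidity method is required")
        if not self.periods:
            raise ConfigError("at least one data period is required")
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        for m in self.methods:
            if m not in cm.METHOD_NAMES:
                raise ConfigError(f"unknown method {m!r}")
        for p in self.periods:
            if p not in _PERIODS:
                raise ConfigError(f"unknown period {p!r}")
        for o in self.outcomes:
            if o not in _OUTCOME_COLS:
                raise ConfigError(f"unknown outcome {o!r}")
        has_scenario = self.scenario is not None
        has_files = self.admissions_path is not None and \
            self.patients_path is not None
        if has_scenario == has_files:
            raise ConfigError(
                "provide either a simulation scenario or a claims/patients "
                "CSV pair (exactly one of the two)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e


def _audit(log_path: Path, records: list[dict]):
    with open(log_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns a name → path map of the outputs."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    audit: list[dict] = [{"stage": "start", "seed": config.seed,
                          "config": {k: str(v) for k, v in
                                     dataclasses.asdict(config).items()}}]
    ss = np.random.SeedSequence(config.seed)
    sim_seed, *boot_seeds = [int(s.generate_state(1)[0] % (2**31))
                             for s in ss.spawn(1 + 64)]
    boot_seeds = iter(boot_seeds)
    outputs: dict[str, Path] = {}

    # --- stage: claims (simulate or load) ---
    if config.scenario is not None:
        sim_config = load_scenario(config.scenario, seed=sim_seed,
                                   n_patients=config.n_patients)
        dataset, truth = simulate_population(sim_config)
        adm_path, pat_path = write_claims(dataset, out)
        gt_path = out / "ground_truth.csv"
        truth.frame.to_csv(gt_path, index=False)
        outputs.update(admissions=adm_path, patients=pat_path,
                       ground_truth=gt_path)
        disease = sim_config.disease
        audit.append({"stage": "simulate", "scenario": str(config.scenario),
                      "seed": sim_seed, "n_patients": sim_config.n_patients})
        dataset = read_claims(adm_path, pat_path)  # exercise the file contract
    else:
        dataset = read_claims(config.admissions_path, config.patients_path)
        disease = config.disease
        audit.append({"stage": "load",
                      "admissions": str(config.admissions_path),
                      "n_admissions": len(dataset.admissions)})

    # --- stage: cohort ---
    cohort, ledger = build_cohort(dataset, disease)
    cdf = cohort_frame(cohort)
    cohort_path = out / "cohort.csv"
    cdf.to_csv(cohort_path, index=False)
    (out / "exclusions.json").write_text(json.dumps(ledger, sort_keys=True))
    outputs["cohort"] = cohort_path
    outputs["exclusions"] = out / "exclusions.json"
    t1 = table1_summary(dataset, cohort)
    t1_path = out / "table1.csv"
    t1.to_csv(t1_path, index=False)
    outputs["table1"] = t1_path
    audit.append({"stage": "cohort", "n_cohort": len(cohort),
                  "exclusions": ledger})

    # --- stage: comorbidity mapping ---
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    for mname in config.methods:
        method = cm.load_method(mname, prior_only=config.prior_only)
        for pname in config.periods:
            mat = cm.profile_matrix(cohort, dataset, method, _PERIODS[pname])
            matrices[(mname, pname)] = mat
            path = out / f"comorbidity_matrix_{mname}_{pname}.csv"
            mat.to_csv(path)
            outputs[f"matrix_{mname}_{pname}"] = path
    audit.append({"stage": "map", "n_matrices": len(matrices)})

    # --- stage: evaluation ---
    rows = []
    designs: dict[tuple[str, str, str], pd.DataFrame] = {}
    for oname in config.outcomes:
        ycol = _OUTCOME_COLS[oname]
        res = evaluate_model(cdf, ycol, None, n_bootstrap=config.n_bootstrap,
                             seed=next(boot_seeds))
        rows.append(_result_row(oname, "baseline", "", res))
        for (mname, pname), mat in matrices.items():
            res = evaluate_model(cdf, ycol, mat,
                                 n_bootstrap=config.n_bootstrap,
                                 seed=next(boot_seeds))
            rows.append(_result_row(oname, mname, pname, res))
            reduced = mat.loc[cdf["patient_id"]].pipe(
                lambda d: d.drop(columns=[c for c in d.columns
                                          if d[c].mean() in (0.0, 1.0)]))
            designs[(oname, mname, pname)] = assemble_design(cdf, reduced)
    eval_df = pd.DataFrame(rows)
    eval_path = out / "evaluation_results.csv"
    eval_df.to_csv(eval_path, index=False)
    outputs["evaluation_results"] = eval_path
    audit.append({"stage": "evaluate", "n_models": len(rows)})

    # --- stage: paired comparisons ---
    if config.compare_methods and len(config.methods) >= 2:
        comp_rows = []
        pairs = [(a, b) for i, a in enumerate(config.methods)
                 for b in config.methods[i + 1:]]
        for oname in config.outcomes:
            y = cdf[_OUTCOME_COLS[oname]].to_numpy(int)
            for pname in config.periods:
                for a, b in pairs:
                    res = paired_bootstrap_compare(
                        designs[(oname, a, pname)],
                        designs[(oname, b, pname)], y,
                        n_reps=config.n_bootstrap, seed=next(boot_seeds))
                    comp_rows.append({
                        "outcome": oname, "period": pname,
                        "method_a": a, "method_b": b,
                        "win_fraction_a": res.win_fraction_a,
                        "tie_fraction": res.tie_fraction,
                        "mean_c_diff": float(res.diffs.mean()),
                        "n_reps": config.n_bootstrap,
                    })
        comp_df = pd.DataFrame(comp_rows)
        comp_path = out / "comparisons.csv"
        comp_df.to_csv(comp_path, index=False)
        outputs["comparisons"] = comp_path
        audit.append({"stage": "compare", "n_pairs": len(comp_rows)})

    # --- stage: report ---
    from .reporting import render_tables
    report = render_tables(out)
    report_path = out / "report.md"
    report_path.write_text(report)
    outputs["report"] = report_path

    _audit(out / "audit.jsonl", audit)
    outputs["audit"] = out / "audit.jsonl"
    return outputs


def _result_row(outcome: str, method: str, period: str, res) -> dict:
    return {
        "outcome": outcome,
        "method": method,
        "period": period,
        "n": res.fit.nobs,
        "g2": "" if res.g2 is None else round(res.g2, 6),
        "df_diff": "" if res.g2_df_diff is None else res.g2_df_diff,
        "df_total": res.g2_df_total,
        "g2_p": "" if res.g2_p is None else res.g2_p,
        "c": round(res.c_statistic, 6),
        "ci_low": round(res.c_ci[0], 6),
        "ci_high": round(res.c_ci[1], 6),
        "n_reps": res.n_bootstrap,
        "converged": res.fit.converged,
        "separation": res.fit.separation,
        "dropped_columns": ";".join(res.dropped_columns),
    }
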