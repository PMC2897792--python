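#!/usr/bin/env python
"""Build the study cohorts from the simulated claims.

Reads the claims written by 01_simulate.py, selects index hospitalizations
(first qualifying admission in 2002), applies the exclusion rules, derives
both mortality outcomes, and writes cohort.csv + exclusions.json plus a
Table-1-style characteristics summary per population.
"""

import argparse
import json
from pathlib import Path

import comorbidikit as ck
from comorbidikit.cohort import cohort_frame

DISEASE = {"ami": "AMI", "copd": "COPD"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for name, disease in DISEASE.items():
        out = args.out / name
        dataset = ck.read_claims(out / "admissions.csv", out / "patients.csv")
        cohort, ledger = ck.build_cohort(dataset, disease)
        cohort_frame(cohort).to_csv(out / "cohort.csv", index=False)
        (out / "exclusions.json").write_text(json.dumps(ledger, sort_keys=True))
        t1 = ck.table1_summary(dataset, cohort)
        t1.to_csv(out / "table1.csv", index=False)
        print(f"[{name}] cohort {len(cohort)} patients; exclusions {ledger}")
        print(t1.to_string(index=False))


if __name__ == "__main__":
    main()
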