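#!/usr/bin/env python
"""Map each cohort to comorbidity flags: 3 measures × 2 data periods.

Writes one patients × categories binary matrix per (method, period) and
prints how many flags each combination sets — the lookback period should
add flags for every method, and the Charlson variants should capture fewer
codes than Elixhauser's broader 30-category net.
"""

import argparse
from pathlib import Path

import pandas as pd

import comorbidikit as ck

DISEASE = {"ami": "AMI", "copd": "COPD"}
PERIODS = {"index_only": ck.INDEX_ONLY, "index_plus_prior": ck.INDEX_PLUS_PRIOR}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for name, disease in DISEASE.items():
        out = args.out / name
        dataset = ck.read_claims(out / "admissions.csv", out / "patients.csv")
        cohort, _ = ck.build_cohort(dataset, disease)
        print(f"[{name}]")
        for mname in ck.METHOD_NAMES:
            method = ck.load_method(mname)
            for pname, period in PERIODS.items():
                mat = ck.profile_matrix(cohort, dataset, method, period)
                mat.to_csv(out / f"comorbidity_matrix_{mname}_{pname}.csv")
                per_patient = mat.sum(axis=1).mean()
                print(f"  {mname:16s} {pname:17s} "
                      f"{int(mat.to_numpy().sum()):6d} flags "
                      f"({per_patient:.2f}/patient)")


if __name__ == "__main__":
    main()
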