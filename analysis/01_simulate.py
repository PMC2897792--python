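#!/usr/bin/env python
"""Generate the two synthetic study populations (AMI-like and COPD-like).

Writes the claims/demographics CSV pair plus ground truth for each
population under results/<population>/, and prints the realized cohort
marginals next to the scenario's targets.
"""

import argparse
from pathlib import Path

import comorbidikit as ck

TARGETS = {   # scenario calibration targets: age mean, in-hosp %, 1-yr %
    "ami": (66.31, 14.94, 27.07),
    "copd": (72.54, 3.02, 22.48),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2002)
    ap.add_argument("--n-patients", type=int, default=None)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for i, name in enumerate(("ami", "copd")):
        config = ck.load_scenario(name, seed=args.seed + i,
                                  n_patients=args.n_patients)
        dataset, truth = ck.simulate_population(config)
        out = args.out / name
        ck.write_claims(dataset, out)
        truth.frame.to_csv(out / "ground_truth.csv", index=False)

        f = truth.frame
        age_t, ih_t, yr_t = TARGETS[name]
        print(f"[{name}] n={config.n_patients}, "
              f"{len(dataset.admissions)} admissions")
        print(f"  age mean {f.age_years.mean():.2f} (target {age_t}); "
              f"in-hospital mortality {100 * f.died_in_hospital.mean():.2f}% "
              f"(target {ih_t}); "
              f"1-year {100 * f.died_within_1yr.mean():.2f}% (target {yr_t})")
        print(f"  wrote {out}/admissions.csv, patients.csv, ground_truth.csv")


if __name__ == "__main__":
    main()
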