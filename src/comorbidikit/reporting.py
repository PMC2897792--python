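"""Human-readable report rendering from the pipeline's result CSVs.

Every number in the report is read from a results file; nothing is
recomputed here, so the report is a faithful view of the machine outputs:
a cohort-characteristics table, a G²(df) grid, a c (95% CI) grid in
"0.737 (0.729-0.753)" style, and the pairwise bootstrap win fractions.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = ["render_tables", "format_c_ci"]


def format_c_ci(c: float, lo: float, hi: float) -> str:
    return f"{c:.3f} ({lo:.3f}-{hi:.3f})"


def _na(msg: str) -> str:
    warnings.warn(msg)
    return "N/A"


def _g2_cell(row) -> str:
    if row["method"] == "baseline" or row["g2"] == "" or pd.isna(row["g2"]):
        return f"N/A ({int(row['df_total'])})"
    return f"{float(row['g2']):.0f} ({int(row['df_total'])})"


def render_tables(out_dir) -> str:
    """Render report.md content from the CSVs under ``out_dir``."""
    out = Path(out_dir)
    lines: list[str] = ["# Comorbidity-measure evaluation report", ""]

    t1_path = out / "table1.csv"
    if t1_path.exists():
        t1 = pd.read_csv(t1_path)
        lines += ["## Cohort characteristics", "",
                  "| Characteristic | Count | Percent / value |",
                  "|---|---|---|"]
        for _, r in t1.iterrows():
            lines.append(f"| {r['characteristic']} | {r['count']} | "
                         f"{r['percent']} |")
        lines.append("")

    eval_path = out / "evaluation_results.csv"
    if eval_path.exists():
        ev = pd.read_csv(eval_path, keep_default_na=False,
                         na_values=[], dtype={"g2": str})
        strata = sorted(set(zip(ev["method"], ev["period"])),
                        key=lambda t: (t[1], t[0]))
        outcomes = list(dict.fromkeys(ev["outcome"]))

        lines += ["## Model fit: G² (df) against the nested baseline", "",
                  "| Model | " + " | ".join(outcomes) + " |",
                  "|---|" + "|".join(["---"] * len(outcomes)) + "|"]
        for method, period in strata:
            label = "Baseline" if method == "baseline" else \
                f"Baseline + {method} [{period}]"
            cells = []
            for oc in outcomes:
                sub = ev[(ev["method"] == method) & (ev["period"] == period)
                         & (ev["outcome"] == oc)]
                cells.append(_g2_cell(sub.iloc[0]) if len(sub) else
                             _na(f"missing stratum {method}/{period}/{oc}"))
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        lines.append("")

        lines += ["## Discrimination: c-statistic (95% bootstrap CI)", "",
                  "| Model | " + " | ".join(outcomes) + " |",
                  "|---|" + "|".join(["---"] * len(outcomes)) + "|"]
        for method, period in strata:
            label = "Baseline" if method == "baseline" else \
                f"Baseline + {method} [{period}]"
            cells = []
            for oc in outcomes:
                sub = ev[(ev["method"] == method) & (ev["period"] == period)
                         & (ev["outcome"] == oc)]
                if len(sub):
                    r = sub.iloc[0]
                    cells.append(format_c_ci(float(r["c"]),
                                             float(r["ci_low"]),
                                             float(r["ci_high"])))
                else:
                    cells.append(_na(f"missing stratum {method}/{period}/{oc}"))
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        lines.append("")

    comp_path = out / "comparisons.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines += ["## Paired bootstrap comparisons (fraction of replicates "
                  "method A outperforms method B)", "",
                  "| Outcome | Period | A | B | A wins | Ties |",
                  "|---|---|---|---|---|---|"]
        for _, r in comp.iterrows():
            lines.append(
                f"| {r['outcome']} | {r['period']} | {r['method_a']} | "
                f"{r['method_b']} | {r['win_fraction_a']:.3f} | "
                f"{r['tie_fraction']:.3f} |")
        lines.append("")

    return "\n".join(lines)
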