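"""Robustness scenarios for the flagging rule.

Repeats flagging and summaries under (a) inclusion restricted to patients
prescribed at least 40 Gy and (b) thresholds of 3 % and 5 % of each
patient's prescription instead of the absolute 200 cGy, and compares the
flagged-fraction-vs-DSC curves across scenarios.

Usage: python analysis/04_sensitivity.py [--seed 42] [--n-patients 30]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from contourdose import (
    AnalysisConfig,
    SimConfig,
    evaluate_cases,
    generate_cohort,
    sensitivity_run,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-patients", type=int, default=30)
    args = ap.parse_args()

    config = AnalysisConfig()
    cases = generate_cohort(SimConfig(seed=args.seed, n_patients=args.n_patients))
    records = evaluate_cases(cases, config)
    scenarios = sensitivity_run(records, config)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    # pooled level only: the full per-organ tables are in each scenario's
    # CohortSummary and regenerable; keep the tracked artifact small
    (results / "sensitivity.json").write_text(
        json.dumps(
            {
                name: {
                    "config": {
                        "flag_threshold_cgy": s.config.flag_threshold_cgy,
                        "relative_threshold_pct": s.config.relative_threshold_pct,
                        "min_plan_dose_cgy": s.config.min_plan_dose_cgy,
                    },
                    "pooled": s.pooled,
                }
                for name, s in scenarios.items()
            },
            indent=1,
            default=float,
        )
        + "\n"
    )
    curves = []
    for name, s in scenarios.items():
        c = s.curves["dsc"].copy()
        c.insert(0, "scenario", name)
        curves.append(c)
    pd.concat(curves).to_csv(results / "sensitivity_dsc_curves.csv", index=False)

    print(f"{'scenario':<20}{'N':>6}{'flagged':>9}{'fraction':>10}")
    for name, s in scenarios.items():
        p = s.pooled
        print(f"{name:<20}{p['N']:>6}{p['n_flagged']:>9}{p['flagged_fraction']:>10.3f}")
    print(f"-> {results/'sensitivity.json'}, sensitivity_dsc_curves.csv")


if __name__ == "__main__":
    main()
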