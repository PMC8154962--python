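"""Develop the prognostic model and the integer prediction rule.

Reads the pooled development cohorts written by 01_simulate_cohorts.py,
applies complete-case filtering, fits the three-predictor logistic model,
checks the bootstrap shrinkage factor, rounds the coefficients into score
weights, refits the score-only model with a study-level random intercept
and tabulates the population-average per-score risks.
"""

import argparse
from pathlib import Path

from dfu_cpr import develop, harmonize


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-bootstrap", type=int, default=200)
    args = ap.parse_args()

    cohorts = harmonize.read_cohort_csv(args.out / "development_cohorts.csv")
    frame, report = harmonize.complete_case_filter(cohorts)
    print(
        f"complete cases: {report.n_retained}/{report.n_input} "
        f"({100 * report.retention:.1f}%), excluded {report.n_excluded}"
    )

    model, cpr = develop.develop_cpr(frame)
    model.shrinkage = develop.shrinkage_factor(
        model, frame, n_bootstrap=args.n_bootstrap, seed=args.seed
    )
    model.to_json(args.out / "prognostic_model.json")
    cpr.to_json(args.out / "cpr.json")
    cpr.risk_table_csv(args.out / "risk_table.csv")

    orx = model.odds_ratios
    print(f"\nprognostic model (n={model.n_used}, events={model.n_events}):")
    for p in model.predictors:
        print(
            f"  {p:16s} coef {model.coefficients[list(model.predictors).index(p)]:5.2f}  "
            f"OR {orx.loc[p, 'odds_ratio']:5.2f} "
            f"({orx.loc[p, 'ci_low']:.2f} to {orx.loc[p, 'ci_high']:.2f})"
        )
    base = model.baseline_risk
    print(f"  baseline risk {base[0]:.3f} ({base[1]:.3f} to {base[2]:.3f})")
    print(f"  shrinkage {model.shrinkage.factor:.3f} (heuristic {model.shrinkage.heuristic:.3f})")

    print(f"\nscore weights: {dict(zip(cpr.predictors, cpr.weights))}")
    print(
        f"score model: per-point OR {cpr.score_model.per_point_or:.2f}, "
        f"between-study SD {cpr.score_model.sigma_u:.3f}"
    )
    print("population-average risk table:")
    for _, row in cpr.risk_table.iterrows():
        print(
            f"  score {int(row['score'])}: n={int(row['n']):5d}  "
            f"risk {row['probability']:.3f} ({row['ci_low']:.3f} to {row['ci_high']:.3f})"
        )


if __name__ == "__main__":
    main()
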