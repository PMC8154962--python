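"""Externally validate the rule on the simulated register.

Reads the fitted rule from results/ and the validation register written by
01_simulate_cohorts.py, computes discrimination (C-statistic with DeLong
CI), calibration (slope, calibration-in-the-large, per-score groups) and the
ROC points, and writes the validation artifacts and the calibration figure.
"""

import argparse
from pathlib import Path

from dfu_cpr import develop, harmonize, validate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cpr = develop.CPRule.from_json(args.out / "cpr.json")
    model = develop.PrognosticModel.from_json(args.out / "prognostic_model.json")
    register = harmonize.read_cohort_csv(args.out / "validation_register.csv")
    register, report_cc = harmonize.complete_case_filter(register)
    print(f"validation register: {report_cc.n_retained} complete cases")

    lp_model = model.linear_predictor(
        register[list(develop.PREDICTORS)].to_numpy(dtype=float)
    )
    report = validate.validate_cpr(cpr, register, prognostic_lp=lp_model)
    report.to_json(args.out / "validation.json")
    if report.groups is not None:
        report.groups.to_csv(args.out / "calibration_groups.csv", index=False)
        validate.plot_calibration(report.groups, args.out / "calibration.svg")
    scores = develop.score_frame(register, cpr.weights)
    points = validate.roc_points(scores, register["ulcer_2yr"].to_numpy(dtype=int))
    points.to_csv(args.out / "roc_points.csv", index=False)

    c, cal = report.c_statistic, report.calibration
    print(f"C-statistic (rule):  {c.value:.3f} ({c.ci_low:.3f} to {c.ci_high:.3f})")
    if report.c_statistic_model is not None:
        cm = report.c_statistic_model
        print(f"C-statistic (model): {cm.value:.3f} ({cm.ci_low:.3f} to {cm.ci_high:.3f})")
    print(f"calibration slope:   {cal.slope:.3f} ({cal.slope_ci[0]:.3f} to {cal.slope_ci[1]:.3f})")
    print(f"calibration-in-the-large: {cal.itl:.3f} ({cal.itl_ci[0]:.3f} to {cal.itl_ci[1]:.3f})")
    print("\nper-score calibration groups:")
    for _, row in report.groups.iterrows():
        print(
            f"  score {int(row['score'])}: n={int(row['n']):5d}  observed {row['observed']:.3f} "
            f"({row['ci_low']:.3f} to {row['ci_high']:.3f})  predicted {row['predicted']:.3f}"
        )


if __name__ == "__main__":
    main()
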