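"""End-to-end pipeline: simulate -> harmonize -> develop -> validate -> decide.

Configured by a YAML/dict config; every stage's artifacts (JSON/CSV/figures)
are written under one output directory together with a human-readable report
and a machine-readable run manifest.  All randomness flows from a single
root seed; identical config and seed give byte-identical JSON/CSV artifacts.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, decision, develop, harmonize, simulate, validate
from .exceptions import PipelineError

ALL_STAGES = ("simulate", "harmonize", "develop", "validate", "decision", "report")


def load_config(config) -> dict:
    """Accept a dict, a path to a YAML file, or None (bundled demo config)."""
    if config is None:
        with resources.files("dfu_cpr.data").joinpath("demo_config.yaml").open() as fh:
            return yaml.safe_load(fh)
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


def _child_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, f"{type(exc).__name__}: {exc}") from exc


def run_pipeline(config=None, stages=ALL_STAGES, seed=None, out_dir=None) -> dict:
    """Run the requested stages; returns a dict of artifacts and objects."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    root_seed = int(cfg.get("seed", 0))
    seedseq = np.random.SeedSequence(root_seed)
    out = Path(cfg.get("out_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)

    artifacts: dict = {"out_dir": str(out)}
    manifest: dict = {
        "config": cfg,
        "seed": root_seed,
        "versions": _versions(),
        "counts": {},
        "stages_run": [],
    }

    frames: list[pd.DataFrame] = []
    dialects: list[str] = []

    # ---- simulate -------------------------------------------------------
    if "simulate" in stages and "inputs" not in cfg:
        sim_cfg = cfg.get("simulate", {})

        def _simulate():
            scenario_file = sim_cfg.get("scenario_file")
            if scenario_file:
                specs = simulate.load_scenario(scenario_file)
            else:
                specs = simulate.development_specs(
                    _child_seed(seedseq, 0),
                    outcome=sim_cfg.get("outcome", "logistic"),
                    sigma_u=sim_cfg.get("sigma_u", simulate.DEFAULT_SIGMA_U),
                    missing_rate=sim_cfg.get("missing_rate", 0.0),
                )
            return simulate.pool_cohorts({s.study_label: simulate.simulate_cohort(s) for s in specs})

        pooled_raw = _stage("simulate", _simulate)
        harmonize.write_cohort_csv(pooled_raw, out / "cohorts.csv")
        artifacts["cohorts_csv"] = str(out / "cohorts.csv")
        manifest["counts"]["simulate"] = {"n_generated": int(len(pooled_raw))}
        manifest["stages_run"].append("simulate")
        frames = [pooled_raw]
        dialects = ["coded"]
    elif "inputs" in cfg:
        for item in cfg["inputs"]:
            frames.append(_stage("harmonize", pd.read_csv, item["path"]))
            dialects.append(item.get("dialect", "coded"))

    # ---- harmonize ------------------------------------------------------
    development = None
    if "harmonize" in stages and frames:
        def _harmonize():
            coded = [harmonize.harmonize_table(f, dialect=d) for f, d in zip(frames, dialects)]
            pooled = pd.concat(coded, ignore_index=True)
            return harmonize.complete_case_filter(pooled)

        development, report = _stage("harmonize", _harmonize)
        manifest["counts"]["harmonize"] = report.to_dict()
        manifest["stages_run"].append("harmonize")

    # ---- develop --------------------------------------------------------
    model = cpr = None
    if "develop" in stages and development is not None:
        dev_cfg = cfg.get("develop", {})

        def _develop():
            model, cpr = develop.develop_cpr(
                development,
                sigma_u=dev_cfg.get("sigma_u"),
                n_quad=dev_cfg.get("n_quad", 15),
            )
            n_boot = dev_cfg.get("n_bootstrap", 200)
            if n_boot:
                model.shrinkage = develop.shrinkage_factor(
                    model, development, n_bootstrap=n_boot, seed=_child_seed(seedseq, 1)
                )
            return model, cpr

        model, cpr = _stage("develop", _develop)
        model.to_json(out / "prognostic_model.json")
        cpr.to_json(out / "cpr.json")
        cpr.risk_table_csv(out / "risk_table.csv")
        artifacts.update(
            prognostic_model=model,
            cpr=cpr,
            prognostic_model_json=str(out / "prognostic_model.json"),
            cpr_json=str(out / "cpr.json"),
            risk_table_csv=str(out / "risk_table.csv"),
        )
        manifest["counts"]["develop"] = {"n_used": model.n_used, "n_events": model.n_events}
        manifest["stages_run"].append("develop")

    # ---- validate -------------------------------------------------------
    register = report_v = None
    if "validate" in stages and cpr is not None:
        val_cfg = cfg.get("validate", {})

        def _validate():
            # self-validation register: predictor mix of the external register,
            # outcomes drawn from the fitted prognostic model
            spec = simulate.CohortSpec(
                study_label="validation-register",
                n=val_cfg.get("n", simulate.VALIDATION_COHORT["n"]),
                prev_mono=simulate.VALIDATION_COHORT["prev_mono"],
                prev_pulse=simulate.VALIDATION_COHORT["prev_pulse"],
                prev_hist=simulate.VALIDATION_COHORT["prev_hist"],
                outcome_model=simulate.LogisticOutcome(
                    model.intercept, *model.coefficients
                ),
                # the register is a new study from the same population of
                # studies: its baseline offset is a fresh draw at the fitted
                # between-study SD
                study_intercept_sd=cpr.score_model.sigma_u,
                seed=_child_seed(seedseq, 2),
            )
            reg = harmonize.add_history(simulate.simulate_cohort(spec))
            reg, _ = harmonize.complete_case_filter(reg)
            lp = model.linear_predictor(reg[list(develop.PREDICTORS)].to_numpy(dtype=float))
            return reg, validate.validate_cpr(cpr, reg, prognostic_lp=lp)

        register, report_v = _stage("validate", _validate)
        report_v.to_json(out / "validation.json")
        if report_v.groups is not None and len(report_v.groups):
            report_v.groups.to_csv(out / "calibration_groups.csv", index=False)
            validate.plot_calibration(report_v.groups, out / "calibration.svg")
        scores_v = develop.score_frame(register, cpr.weights)
        points = validate.roc_points(scores_v, register["ulcer_2yr"].to_numpy(dtype=int))
        points.to_csv(out / "roc_points.csv", index=False)
        artifacts.update(
            validation=report_v,
            validation_json=str(out / "validation.json"),
            roc_points_csv=str(out / "roc_points.csv"),
        )
        manifest["counts"]["validate"] = {
            "n_used": report_v.n_used,
            "n_events": report_v.n_events,
        }
        manifest["stages_run"].append("validate")

    # ---- decision -------------------------------------------------------
    curve = rec = None
    if "decision" in stages and cpr is not None and register is not None:
        dec_cfg = cfg.get("decision", {})

        def _decide():
            grid_cfg = dec_cfg.get("grid")
            grid = (
                None
                if grid_cfg is None
                else np.round(
                    np.arange(grid_cfg["lo"], grid_cfg["hi"] + 1e-9, grid_cfg["step"]), 10
                )
            )
            scores_v = develop.score_frame(register, cpr.weights)
            risks = cpr.predicted_risk(scores_v)
            curve = decision.decision_curve(
                register["ulcer_2yr"].to_numpy(dtype=int), risks, thresholds=grid
            )
            rec = decision.recommend_threshold(
                curve,
                cpr.risk_table,
                clinical_range=tuple(
                    dec_cfg.get("clinical_range", decision.DEFAULT_CLINICAL_RANGE)
                ),
            )
            return curve, rec

        curve, rec = _stage("decision", _decide)
        curve.to_csv(out / "decision_curve.csv")
        rec.to_json(out / "recommendation.json")
        decision.plot_decision_curve(curve, out / "decision_curve.svg")
        artifacts.update(
            decision_curve=curve,
            recommendation=rec,
            decision_curve_csv=str(out / "decision_curve.csv"),
            recommendation_json=str(out / "recommendation.json"),
        )
        manifest["stages_run"].append("decision")

    # ---- report ---------------------------------------------------------
    if "report" in stages:
        text = _render_report(model, cpr, report_v, rec)
        (out / "report.txt").write_text(text)
        artifacts["report_txt"] = str(out / "report.txt")
        manifest["stages_run"].append("report")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    artifacts["manifest_json"] = str(out / "manifest.json")
    artifacts["manifest"] = manifest
    return artifacts


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "dfu_cpr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _render_report(model, cpr, report_v, rec) -> str:
    lines = ["Diabetic foot ulcer prediction rule: pipeline report", "=" * 52, ""]
    if model is not None:
        risk = model.baseline_risk
        lines.append(f"Prognostic model: n={model.n_used}, events={model.n_events}")
        orx = model.odds_ratios
        for p in model.predictors:
            lines.append(
                f"  {p}: OR {orx.loc[p, 'odds_ratio']:.2f} "
                f"(95% CI {orx.loc[p, 'ci_low']:.2f} to {orx.loc[p, 'ci_high']:.2f})"
            )
        lines.append(f"  baseline risk {risk[0]:.3f} (95% CI {risk[1]:.3f} to {risk[2]:.3f})")
        if model.shrinkage is not None:
            s = model.shrinkage
            lines.append(f"  shrinkage factor {s.factor:.3f} (heuristic {s.heuristic:.3f})")
        lines.append("")
    if cpr is not None:
        lines.append(f"Score weights: {dict(zip(cpr.predictors, cpr.weights))}")
        lines.append(f"Per-point OR: {cpr.score_model.per_point_or:.2f}; "
                     f"between-study SD: {cpr.score_model.sigma_u:.3f}")
        lines.append("Risk table (population-average):")
        for _, row in cpr.risk_table.iterrows():
            lines.append(
                f"  score {int(row['score'])}: n={int(row['n'])}, "
                f"risk {row['probability']:.3f} "
                f"({row['ci_low']:.3f} to {row['ci_high']:.3f})"
            )
        lines.append("")
    if report_v is not None:
        c = report_v.c_statistic
        cal = report_v.calibration
        lines.append(f"Validation (n={report_v.n_used}, events={report_v.n_events}):")
        lines.append(f"  C-statistic {c.value:.3f} (95% CI {c.ci_low:.3f} to {c.ci_high:.3f})")
        lines.append(
            f"  calibration slope {cal.slope:.3f} "
            f"({cal.slope_ci[0]:.3f} to {cal.slope_ci[1]:.3f})"
        )
        lines.append(
            f"  calibration-in-the-large {cal.itl:.3f} "
            f"({cal.itl_ci[0]:.3f} to {cal.itl_ci[1]:.3f})"
        )
        if report_v.c_statistic_model is not None:
            lines.append(
                f"  prognostic-model C-statistic {report_v.c_statistic_model.value:.3f}"
            )
        lines.append("")
    if rec is not None:
        if rec:
            lines.append(
                f"Recommendation: refer at score >= {rec.score} "
                f"(predicted risk {rec.risk:.3f} or more)"
            )
        else:
            lines.append(f"Recommendation: none ({rec.reason})")
    lines.append("")
    return "\n".join(lines)
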