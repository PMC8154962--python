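"""Validation metrics: C-statistic vs pair-counting oracle, calibration
refits on simulated truth, grouped calibration rows, ROC identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from dfu_cpr import develop, harmonize, simulate, validate
from dfu_cpr.exceptions import ValidationError
from dfu_cpr.validate import (
    c_statistic,
    calibration_groups,
    calibration_metrics,
    clopper_pearson,
    roc_auc,
    roc_points,
    validate_scores,
)


def c_oracle(scores, outcomes):
    """Brute force over all event x non-event pairs, ties counted half."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_c_statistic_worked_example():
    assert c_statistic([1, 2, 2, 3], [0, 0, 1, 1]).value == pytest.approx(0.875)


def test_c_statistic_extremes():
    perfect = c_statistic([0, 0, 1, 1, 2, 2], [0, 0, 0, 0, 1, 1])
    assert perfect.value == 1.0
    rng = np.random.default_rng(1)
    scores = rng.integers(0, 5, 20_000)
    outcomes = rng.permutation((rng.random(20_000) < 0.05).astype(int))
    assert c_statistic(scores, outcomes).value == pytest.approx(0.5, abs=0.03)


def test_c_statistic_brute_force_oracle():
    """1000 random instances (n <= 200) against exhaustive pair counting."""
    rng = np.random.default_rng(2)
    for _ in range(1000):
        n = rng.integers(4, 200)
        scores = rng.integers(0, 6, n)
        outcomes = rng.random(n) < rng.uniform(0.1, 0.9)
        if outcomes.sum() in (0, n):
            continue
        res = c_statistic(scores, outcomes.astype(int), ci=False)
        assert res.value == pytest.approx(c_oracle(scores, outcomes), abs=1e-12)


def test_c_statistic_errors():
    with pytest.raises(ValidationError):
        c_statistic([1, 2], [1, 1])
    with pytest.raises(ValidationError):
        c_statistic([1, 2], [0, 0])


def test_c_statistic_delong_ci_reasonable(register_20k):
    res = c_statistic(register_20k["score"], register_20k["ulcer_2yr"])
    assert res.ci_low < res.value < res.ci_high
    assert 0.005 < res.se < 0.05
    # large-sample CI roughly matches a bootstrap check
    rng = np.random.default_rng(3)
    n = len(register_20k)
    s = register_20k["score"].to_numpy()
    y = register_20k["ulcer_2yr"].to_numpy()
    boot = []
    for _ in range(60):
        idx = rng.integers(0, n, n)
        if y[idx].sum() in (0, n):
            continue
        boot.append(c_statistic(s[idx], y[idx], ci=False).value)
    assert res.se == pytest.approx(np.std(boot, ddof=1), rel=0.5)


@settings(derandomize=True, max_examples=100)
@given(st.data())
def test_c_statistic_invariant_under_monotone_transform(data):
    n = data.draw(st.integers(6, 60))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    scores = rng.integers(0, 5, n).astype(float)
    outcomes = (rng.random(n) < 0.4).astype(int)
    if outcomes.sum() in (0, n):
        return
    a = c_statistic(scores, outcomes, ci=False).value
    b = c_statistic(np.exp(2.0 * scores) - 3.0, outcomes, ci=False).value
    assert a == pytest.approx(b, abs=1e-12)


# --- calibration ----------------------------------------------------------

def test_calibration_perfect_predictor(register_20k, published_score_model):
    """Outcomes simulated from the supplied linear predictor give slope ~1,
    calibration-in-the-large ~0."""
    lp = published_score_model.linear_predictor(register_20k["score"])
    res = calibration_metrics(lp, register_20k["ulcer_2yr"])
    assert res.slope == pytest.approx(1.0, abs=0.1)
    assert res.itl == pytest.approx(0.0, abs=0.1)
    assert res.slope_ci[0] < res.slope < res.slope_ci[1]


def test_calibration_overdispersed_predictor(register_20k, published_score_model):
    """Validating twice-the-true-logit halves the slope."""
    lp_true = published_score_model.linear_predictor(register_20k["score"])
    res = calibration_metrics(2.0 * lp_true, register_20k["ulcer_2yr"])
    assert res.slope == pytest.approx(0.5, abs=0.06)


def test_calibration_offset_shift():
    """Outcomes from a +0.5-shifted logit validated with the unshifted
    predictor give calibration-in-the-large ~ +0.5."""
    rng = np.random.default_rng(9)
    scores = rng.integers(0, 5, 20_000)
    lp = simulate.SCORE_ALPHA + simulate.SCORE_GAMMA * scores
    y = (rng.random(20_000) < expit(lp + 0.5)).astype(int)
    res = calibration_metrics(lp, y)
    assert res.itl == pytest.approx(0.5, abs=0.12)


def test_calibration_constant_predictor_rejected():
    with pytest.raises(ValidationError, match="constant"):
        calibration_metrics(np.zeros(100), np.r_[np.ones(10), np.zeros(90)].astype(int))


def test_calibration_coverage_over_replicates():
    """Slope CIs cover 1 and ITL CIs cover 0 with ~95% frequency over 200
    self-consistent replicates."""
    cover_slope = cover_itl = 0
    reps = 200
    for i in range(reps):
        reg = simulate.simulate_score_register(3324, seed=1000 + i)
        lp = simulate.SCORE_ALPHA + simulate.SCORE_GAMMA * reg["score"].to_numpy()
        res = calibration_metrics(lp, reg["ulcer_2yr"])
        cover_slope += res.slope_ci[0] <= 1.0 <= res.slope_ci[1]
        cover_itl += res.itl_ci[0] <= 0.0 <= res.itl_ci[1]
    assert 0.90 <= cover_slope / reps <= 0.99
    assert 0.90 <= cover_itl / reps <= 0.99


# --- grouped calibration --------------------------------------------------

def test_calibration_groups_counting(published_risk_table):
    groups = calibration_groups([0] * 100, [1, 1] + [0] * 98, published_risk_table)
    assert len(groups) == 1
    row = groups.iloc[0]
    assert row["n"] == 100 and row["observed"] == pytest.approx(0.02)
    assert row["predicted"] == pytest.approx(0.024)
    lo, hi = clopper_pearson(2, 100)
    assert row["ci_low"] == pytest.approx(lo) and row["ci_high"] == pytest.approx(hi)
    assert lo < 0.02 < hi


def test_calibration_groups_empty_level_omitted(published_risk_table):
    scores = [0] * 50 + [1] * 50          # nobody at scores 2-4
    y = [0] * 99 + [1]
    groups = calibration_groups(scores, y, published_risk_table)
    assert groups["score"].tolist() == [0, 1]


def test_calibration_groups_unknown_score_rejected(published_risk_table):
    with pytest.raises(ValidationError):
        calibration_groups([0, 7], [0, 1], published_risk_table)


def test_calibration_groups_self_consistency(register_20k, published_risk_table):
    """On a register simulated from the rule itself, predicted risks fall
    inside the observed CIs in >= 4 of 5 score groups."""
    groups = calibration_groups(
        register_20k["score"], register_20k["ulcer_2yr"], published_risk_table
    )
    inside = (
        (groups["predicted"] >= groups["ci_low"]) & (groups["predicted"] <= groups["ci_high"])
    ).sum()
    assert inside >= 4


# --- ROC ------------------------------------------------------------------

def test_roc_points_identity_with_c_statistic():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = rng.integers(6, 150)
        scores = rng.integers(0, 5, n)
        y = (rng.random(n) < 0.3).astype(int)
        if y.sum() in (0, n):
            continue
        pts = roc_points(scores, y)
        assert roc_auc(pts) == pytest.approx(
            c_statistic(scores, y, ci=False).value, abs=1e-12
        )


def test_roc_points_shapes():
    pts = roc_points([0, 0, 1, 1], [0, 0, 1, 1])          # perfect separation
    assert ((pts["fpr"] == 0) & (pts["tpr"] == 1)).any()
    binary = roc_points([0, 1, 0, 1], [0, 1, 1, 0])
    assert len(binary) == 3


# --- assembled validation -------------------------------------------------

def test_validate_scores_report(register_20k, published_score_model, published_risk_table):
    report = validate_scores(
        published_score_model,
        register_20k["score"],
        register_20k["ulcer_2yr"],
        risk_table=published_risk_table,
    )
    assert report.n_used == 20_000
    assert report.groups["n"].sum() == report.n_used
    assert report.calibration.slope == pytest.approx(1.0, abs=0.1)
    assert 0.7 < report.c_statistic.value < 0.9
    d = report.to_dict()
    assert set(d) >= {"c_statistic", "calibration", "groups", "n_used", "n_events"}


def test_cpr_vs_prognostic_model_discrimination():
    """Scoring loses little discrimination relative to the full model on the
    same simulated register (C difference < 0.02)."""
    spec = simulate.CohortSpec(
        "reg", 20_000,
        prev_mono=0.207, prev_pulse=0.140, prev_hist=0.057,
        outcome_model=simulate.POOLED_MODEL, seed=17,
    )
    frame = harmonize.add_history(simulate.simulate_cohort(spec))
    scores = develop.score_frame(frame, (1, 1, 2))
    x = frame[list(develop.PREDICTORS)].to_numpy(dtype=float)
    lp = simulate.POOLED_MODEL.intercept + x @ simulate.POOLED_MODEL.coefficients
    y = frame["ulcer_2yr"].to_numpy(dtype=int)
    c_score = c_statistic(scores, y, ci=False).value
    c_model = c_statistic(lp, y, ci=False).value
    assert abs(c_score - c_model) < 0.02


def test_plots_write_files(tmp_path, register_20k, published_risk_table):
    groups = calibration_groups(
        register_20k["score"], register_20k["ulcer_2yr"], published_risk_table
    )
    validate.plot_calibration(groups, tmp_path / "cal.svg")
    pts = roc_points(register_20k["score"], register_20k["ulcer_2yr"])
    validate.plot_roc(pts, tmp_path / "roc.png")
    assert (tmp_path / "cal.svg").stat().st_size > 0
    assert (tmp_path / "roc.png").stat().st_size > 0
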