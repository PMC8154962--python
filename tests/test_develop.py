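"""Model development: logistic fit vs closed forms, shrinkage behaviour,
score conversion, random-intercept score model and marginal risks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from dfu_cpr import develop, harmonize, simulate
from dfu_cpr.develop import (
    CPRule,
    ZeroWeightWarning,
    build_risk_table,
    convert_to_cpr,
    fit_logistic,
    fit_score_model,
    marginal_probability,
    attenuated_probability,
    population_average_risk,
    score,
    score_frame,
    score_model_from_published,
    shrinkage_factor,
)
from dfu_cpr.exceptions import FitError, SeparationError, ValidationError


def _frame(x_cols: dict, y):
    data = {k: pd.array(v, dtype="Int64") for k, v in x_cols.items()}
    data["ulcer_2yr"] = pd.array(y, dtype="Int64")
    return pd.DataFrame(data)


def _two_by_two(n11, n10, n01, n00):
    """exposed: n11 events / n10 non-events; unexposed: n01 / n00."""
    x = [1] * (n11 + n10) + [0] * (n01 + n00)
    y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    return _frame({"exposed": x}, y)


def test_logistic_matches_2x2_closed_form():
    """Saturated single-predictor fit equals the contingency-table log-OR."""
    frame = _two_by_two(10, 40, 5, 45)
    model = fit_logistic(frame, predictors=("exposed",))
    assert model.coefficients[0] == pytest.approx(math.log((10 * 45) / (40 * 5)), abs=1e-6)
    assert model.intercept == pytest.approx(math.log(5 / 45), abs=1e-6)


def test_logistic_random_2x2_tables():
    """Closed-form OR oracle over randomized saturated tables."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        cells = rng.integers(1, 60, size=4)
        frame = _two_by_two(*cells)
        model = fit_logistic(frame, predictors=("exposed",))
        n11, n10, n01, n00 = cells
        assert model.coefficients[0] == pytest.approx(
            math.log((n11 * n00) / (n10 * n01)), abs=1e-6
        )


def test_odds_ratio_exp_round_trip(dev_frame_logistic):
    model = fit_logistic(dev_frame_logistic)
    np.testing.assert_allclose(
        model.odds_ratios["odds_ratio"].to_numpy(), np.exp(model.coefficients), rtol=1e-12
    )
    orx = model.odds_ratios
    assert ((orx["ci_low"] < orx["odds_ratio"]) & (orx["odds_ratio"] < orx["ci_high"])).all()


def test_logistic_recovers_generating_coefficients(dev_frame_logistic):
    """Development-scale fit lands within Wald 95% CIs of the truth."""
    model = fit_logistic(dev_frame_logistic)
    truth = np.array([1.11, 0.70, 1.95])
    se = model.standard_errors[1:]
    assert np.all(np.abs(model.coefficients - truth) < 1.96 * se * 1.5)
    base = model.baseline_risk
    assert base[1] < base[0] < base[2]
    # covariance positive semi-definite
    assert np.all(np.linalg.eigvalsh(model.covariance) > -1e-12)


def test_logistic_degenerate_inputs():
    with pytest.raises(FitError, match="event"):
        fit_logistic(_frame({"exposed": [0, 1, 0, 1]}, [0, 0, 0, 0]), predictors=("exposed",))
    with pytest.raises(FitError, match="constant"):
        fit_logistic(_frame({"exposed": [1, 1, 1, 1]}, [0, 1, 0, 1]), predictors=("exposed",))
    with pytest.raises(ValidationError, match="missing"):
        frame = _frame({"exposed": [0, 1, None, 1]}, [0, 1, 0, 1])
        fit_logistic(frame, predictors=("exposed",))


def test_logistic_complete_separation_named():
    frame = _two_by_two(20, 0, 0, 20)  # exposure perfectly predicts outcome
    with pytest.raises(SeparationError) as err:
        fit_logistic(frame, predictors=("exposed",))
    assert "exposed" in err.value.predictors


def test_shrinkage_near_one_at_development_scale(dev_frame_logistic):
    model = fit_logistic(dev_frame_logistic)
    res = shrinkage_factor(model, dev_frame_logistic, n_bootstrap=200, seed=0)
    assert 0.95 <= res.factor <= 1.02
    assert 0.9 <= res.heuristic <= 1.0


def test_shrinkage_detects_small_sample_overfit():
    """n=60 with 8 noise predictors and 10 events is overfitted: s < 0.9."""
    rng = np.random.default_rng(4)
    n = 60
    frame = pd.DataFrame({f"x{j}": rng.standard_normal(n) for j in range(8)})
    frame["ulcer_2yr"] = pd.array([1] * 10 + [0] * (n - 10), dtype="Int64")
    model = fit_logistic(frame, predictors=tuple(f"x{j}" for j in range(8)))
    res = shrinkage_factor(model, frame, n_bootstrap=100, seed=1)
    assert res.factor < 0.9


def test_shrinkage_deterministic(dev_frame_logistic):
    model = fit_logistic(dev_frame_logistic)
    a = shrinkage_factor(model, dev_frame_logistic, n_bootstrap=60, seed=5)
    b = shrinkage_factor(model, dev_frame_logistic, n_bootstrap=60, seed=5)
    assert a == b


def test_shrinkage_approaches_one_with_n():
    """s -> 1 as n grows at fixed predictor count."""
    truth = simulate.LogisticOutcome(float(logit(0.1)), 1.0, 0.6, 1.5)
    factors = []
    for n in (200, 2000, 20000):
        spec = simulate.CohortSpec("s", n, 0.3, 0.3, 0.2, truth, seed=7)
        frame = harmonize.add_history(simulate.simulate_cohort(spec))
        model = fit_logistic(frame)
        factors.append(shrinkage_factor(model, frame, n_bootstrap=100, seed=2).factor)
    assert factors[2] > factors[0]
    assert factors[2] > 0.98
    assert factors[0] < 0.97


def test_convert_to_cpr_rounding():
    assert convert_to_cpr([1.11, 0.70, 1.95]) == (1, 1, 2)
    assert convert_to_cpr([1.0, 1.0, 2.0]) == (1, 1, 2)
    with pytest.warns(ZeroWeightWarning):
        assert convert_to_cpr([0.49, 1.51, 2.5]) == (0, 2, 3)


def test_score_enumeration():
    weights = (1, 1, 2)
    combos = [(m, p, h) for m in (0, 1) for p in (0, 1) for h in (0, 1)]
    scores = sorted(score(c, weights) for c in combos)
    assert scores == [0, 1, 1, 2, 2, 3, 3, 4]
    assert score({"mono_insensate": 1, "pulses_absent": 0, "history": 1}, weights) == 3
    with pytest.raises(ValidationError):
        score((1, None, 0), weights)


def test_score_frame_matches_scalar():
    frame = _frame(
        {"mono_insensate": [0, 1, 1], "pulses_absent": [0, 0, 1], "history": [0, 1, 1]},
        [0, 0, 1],
    )
    assert score_frame(frame, (1, 1, 2)).tolist() == [0, 3, 4]


# --- score model ----------------------------------------------------------

def test_score_model_single_study_recovery():
    """Single-study fit recovers (alpha, gamma) within ~Wald intervals."""
    reg = simulate.simulate_score_register(30_000, seed=21)
    sm_fit = fit_score_model(reg["score"], reg["ulcer_2yr"])
    se = np.sqrt(np.diag(sm_fit.covariance))
    assert abs(sm_fit.alpha - simulate.SCORE_ALPHA) < 3 * se[0]
    assert abs(sm_fit.gamma - simulate.SCORE_GAMMA) < 3 * se[1]
    assert sm_fit.sigma_u == 0.0


def test_score_model_requires_variation():
    with pytest.raises(FitError):
        fit_score_model([1, 1, 1, 1], [0, 1, 0, 1])
    with pytest.raises(FitError):
        fit_score_model([0, 1, 2, 3], [0, 0, 0, 0])


def test_score_model_sigma_boundary_when_truth_zero():
    """With no between-study heterogeneity the estimated SD sits near 0 and
    (alpha, gamma) match the pooled fixed-effect fit."""
    rng = np.random.default_rng(3)
    regs = [
        simulate.simulate_score_register(4000, seed=100 + j, sigma_u=0.0) for j in range(4)
    ]
    scores = np.concatenate([r["score"] for r in regs])
    y = np.concatenate([r["ulcer_2yr"] for r in regs])
    labels = np.concatenate([[j] * 4000 for j in range(4)])
    glmm = fit_score_model(scores, y, study_labels=labels)
    pooled = fit_score_model(scores, y)
    assert glmm.sigma_u < 0.1
    assert glmm.alpha == pytest.approx(pooled.alpha, abs=0.05)
    assert glmm.gamma == pytest.approx(pooled.gamma, abs=0.05)


def test_score_model_recovers_between_study_sd():
    """Four studies with fixed distinct baseline offsets: the estimated
    between-study SD recovers the RMS offset within 50% relative error."""
    offsets = (-0.6, -0.2, 0.2, 0.6)
    target = float(np.sqrt(np.mean(np.square(offsets))))  # 0.447
    regs = []
    labels = []
    for j, off in enumerate(offsets):
        r = simulate.simulate_score_register(
            8000, seed=50 + j, alpha=simulate.SCORE_ALPHA + off, sigma_u=0.0
        )
        regs.append(r)
        labels.append(np.full(len(r), j))
    scores = np.concatenate([r["score"] for r in regs])
    y = np.concatenate([r["ulcer_2yr"] for r in regs])
    glmm = fit_score_model(scores, y, study_labels=np.concatenate(labels))
    assert abs(glmm.sigma_u - target) / target < 0.5
    assert abs(glmm.gamma - simulate.SCORE_GAMMA) < 0.1


# --- marginalization ------------------------------------------------------

def test_marginal_probability_degenerate_and_symmetry():
    assert marginal_probability(0.7, 0.0) == pytest.approx(float(expit(0.7)), abs=1e-15)
    for sigma in (0.2, 0.7, 1.5):
        assert marginal_probability(0.0, sigma) == pytest.approx(0.5, abs=1e-12)


def test_marginal_probability_monte_carlo_oracle():
    """Quadrature matches a 10^6-draw Monte-Carlo average to 3 decimals."""
    rng = np.random.default_rng(12)
    u = rng.standard_normal(1_000_000)
    for eta in (-3.0, -1.2, 0.4):
        mc = float(expit(eta + 1.0 * u).mean())
        assert marginal_probability(eta, 1.0) == pytest.approx(mc, abs=1e-3)


def test_attenuation_approximation_close():
    """Analytic attenuation approximation tracks quadrature closely for
    sigma_u <= 1 (the 0.346 attenuation constant has a known worst-case
    error just above 0.006 near sigma = 1)."""
    for sigma in (0.0, 0.3, 0.6, 1.0):
        for eta in np.linspace(-4, 1, 11):
            assert abs(
                marginal_probability(eta, sigma) - attenuated_probability(eta, sigma)
            ) < 0.0075


def test_jensen_attenuation():
    """Marginal risk with sigma_u > 0 is pulled toward 0.5 relative to the
    conditional risk at the same linear predictor."""
    for eta in (-3.0, -1.0, 1.0, 3.0):
        marginal = marginal_probability(eta, 0.8)
        conditional = float(expit(eta))
        assert abs(marginal - 0.5) < abs(conditional - 0.5)


def test_population_average_risk_published_parameters(published_score_model):
    """Printed baseline risk and per-point OR reproduce the published
    per-score risks within 1.5% relative."""
    published = {1: 0.060, 2: 0.140, 3: 0.292}
    for k, p in published.items():
        est = population_average_risk(published_score_model, k)
        assert abs(est.probability - p) / p < 0.015


def test_population_average_risk_validates_range(published_score_model):
    with pytest.raises(ValidationError):
        population_average_risk(published_score_model, -1)
    with pytest.raises(ValidationError):
        population_average_risk(published_score_model, 5, max_score=4)


def test_risk_table_monotone_and_flat():
    sm0 = score_model_from_published(0.024, 2.57, sigma_u=0.4)
    scores = np.repeat([0, 1, 2, 3, 4], 10)
    table = build_risk_table(sm0, scores)
    assert (np.diff(table["probability"]) > 0).all()
    assert table["probability"].between(0, 1, inclusive="neither").all()
    flat = build_risk_table(score_model_from_published(0.1, 1.0), scores)
    assert np.allclose(flat["probability"], 0.1, atol=1e-12)


def test_delta_ci_close_to_marginalized_ci():
    reg = simulate.simulate_score_register(20_000, seed=2)
    fitted = fit_score_model(reg["score"], reg["ulcer_2yr"])
    for k in range(5):
        a = population_average_risk(fitted, k, ci_method="marginalize")
        b = population_average_risk(fitted, k, ci_method="delta")
        assert a.ci_low == pytest.approx(b.ci_low, abs=0.01)
        assert a.ci_high == pytest.approx(b.ci_high, abs=0.015)


def test_develop_cpr_end_to_end(dev_frame_logistic):
    model, cpr = develop.develop_cpr(dev_frame_logistic)
    assert cpr.weights == (1, 1, 2)
    assert cpr.max_score == 4
    assert list(cpr.risk_table["score"]) == [0, 1, 2, 3, 4]
    assert (np.diff(cpr.risk_table["probability"]) > 0).all()
    assert cpr.risk_table["n"].sum() == len(dev_frame_logistic)
    risks = cpr.predicted_risk([0, 4])
    assert risks[0] < risks[1]
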