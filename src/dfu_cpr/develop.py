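"""Prognostic model development and conversion to the integer prediction rule.

The prognostic model is a logistic regression of the 2-year ulcer outcome on
three binary predictors (monofilament insensitivity, any absent pedal pulse,
history of ulcer or amputation), all forced into the model.  Adequacy of the
sample size is checked with a bootstrap uniform shrinkage factor.  The model
is converted to an integer clinical prediction rule (CPR) by rounding each
coefficient to the nearest integer, and the rule's per-score risks are
estimated population-averaged: a logistic model with the score as the single
predictor and a normal study-level random intercept is fitted by adaptive
Gauss–Hermite maximum likelihood, and each score's risk is the conditional
probability marginalized over the random-intercept distribution (Pavlou-style
population-average estimate).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import FitError, SeparationError, ValidationError

Z95 = norm.ppf(0.975)

PREDICTORS = ("mono_insensate", "pulses_absent", "history")
OUTCOME = "ulcer_2yr"

IRLS_TOL = 1e-10
IRLS_MAXITER = 100


# --------------------------------------------------------------------------
# pooled logistic prognostic model
# --------------------------------------------------------------------------

@dataclass
class PrognosticModel:
    """Fitted three-predictor logistic model on the log-odds scale."""

    predictors: tuple
    intercept: float
    coefficients: np.ndarray          # aligned with `predictors`
    covariance: np.ndarray            # (1+k)x(1+k), intercept first
    n_used: int
    n_events: int
    shrinkage: Optional["ShrinkageResult"] = None

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def odds_ratios(self) -> pd.DataFrame:
        se = self.standard_errors[1:]
        lo = np.exp(self.coefficients - Z95 * se)
        hi = np.exp(self.coefficients + Z95 * se)
        return pd.DataFrame(
            {"odds_ratio": np.exp(self.coefficients), "ci_low": lo, "ci_high": hi},
            index=list(self.predictors),
        )

    @property
    def baseline_risk(self) -> tuple[float, float, float]:
        """Risk with all predictors 0, with Wald 95% CI (point, low, high)."""
        se = self.standard_errors[0]
        return (
            float(expit(self.intercept)),
            float(expit(self.intercept - Z95 * se)),
            float(expit(self.intercept + Z95 * se)),
        )

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.intercept + x @ self.coefficients

    def to_dict(self) -> dict:
        orx = self.odds_ratios
        risk = self.baseline_risk
        d = {
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": {p: float(c) for p, c in zip(self.predictors, self.coefficients)},
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "odds_ratios": {
                p: {
                    "odds_ratio": float(orx.loc[p, "odds_ratio"]),
                    "ci_low": float(orx.loc[p, "ci_low"]),
                    "ci_high": float(orx.loc[p, "ci_high"]),
                }
                for p in self.predictors
            },
            "baseline_risk": {"point": risk[0], "ci_low": risk[1], "ci_high": risk[2]},
            "n_used": self.n_used,
            "n_events": self.n_events,
        }
        if self.shrinkage is not None:
            d["shrinkage"] = self.shrinkage.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PrognosticModel":
        predictors = tuple(d["predictors"])
        return cls(
            predictors=predictors,
            intercept=float(d["intercept"]),
            coefficients=np.array([d["coefficients"][p] for p in predictors]),
            covariance=np.array(d["covariance"]),
            n_used=int(d["n_used"]),
            n_events=int(d["n_events"]),
        )

    @classmethod
    def from_json(cls, path) -> "PrognosticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _design(frame: pd.DataFrame, predictors: Sequence[str], outcome: str):
    for col in (*predictors, outcome):
        if col not in frame.columns:
            raise ValidationError(f"fit_logistic: missing column {col!r}")
        if frame[col].isna().any():
            raise ValidationError(
                f"fit_logistic: column {col!r} has missing values; apply complete_case_filter first"
            )
    y = frame[outcome].to_numpy(dtype=float)
    x = frame[list(predictors)].to_numpy(dtype=float)
    return x, y


def _separating_predictors(x: np.ndarray, y: np.ndarray, predictors) -> list[str]:
    """Binary predictors with an empty outcome-by-predictor cell (quasi-separation)."""
    flagged = []
    for j, name in enumerate(predictors):
        xj = x[:, j]
        if set(np.unique(xj)) <= {0.0, 1.0}:
            cells = [((xj == a) & (y == b)).sum() for a in (0, 1) for b in (0, 1)]
            if 0 in cells:
                flagged.append(name)
    return flagged


def fit_logistic(
    frame: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    outcome: str = OUTCOME,
) -> PrognosticModel:
    """Maximum-likelihood logistic fit (IRLS) with Wald covariance.

    All listed predictors are retained regardless of significance.  Raises on
    degenerate inputs: no events / no non-events, a constant predictor, or
    complete separation (the offending predictor is named when identifiable).
    """
    x, y = _design(frame, predictors, outcome)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise FitError(
            f"fit_logistic: need at least one event and one non-event (events={n_events}, n={len(y)})"
        )
    for j, name in enumerate(predictors):
        if np.unique(x[:, j]).size < 2:
            raise FitError(f"fit_logistic: predictor {name!r} is constant")
    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=IRLS_TOL, maxiter=IRLS_MAXITER
            )
    except PerfectSeparationError as exc:
        culprits = _separating_predictors(x, y, predictors)
        raise SeparationError(
            f"fit_logistic: complete separation (predictors: {culprits or 'not identified'})",
            culprits,
        ) from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))) or np.any(
        np.abs(params) > 15
    ):
        culprits = _separating_predictors(x, y, predictors)
        raise SeparationError(
            f"fit_logistic: diverging estimates suggest separation (predictors: {culprits or 'not identified'})",
            culprits,
        )
    if not res.converged:
        raise FitError("fit_logistic: IRLS did not converge within the iteration limit")
    return PrognosticModel(
        predictors=tuple(predictors),
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        covariance=np.asarray(res.cov_params()),
        n_used=len(y),
        n_events=n_events,
    )


# --------------------------------------------------------------------------
# bootstrap shrinkage
# --------------------------------------------------------------------------

@dataclass
class ShrinkageResult:
    """Bootstrap uniform shrinkage factor with a percentile interval."""

    factor: float
    ci_low: float
    ci_high: float
    heuristic: float              # (model chi2 - df) / model chi2
    n_bootstrap: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "heuristic": self.heuristic,
            "n_bootstrap": self.n_bootstrap,
            "n_dropped": self.n_dropped,
        }


def _calibration_slope_raw(lp: np.ndarray, y: np.ndarray) -> float:
    design = sm.add_constant(lp, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            tol=IRLS_TOL, maxiter=IRLS_MAXITER
        )
    return float(res.params[1])


def shrinkage_factor(
    model: PrognosticModel,
    frame: pd.DataFrame,
    n_bootstrap: int = 500,
    seed: int = 0,
    outcome: str = OUTCOME,
) -> ShrinkageResult:
    """Bootstrap estimate of the uniform shrinkage factor s.

    For each bootstrap resample the model is refitted and the calibration
    slope of the resample model's linear predictor on the *original* data is
    recorded; s is the mean slope (s ≈ 1 means the sample size is adequate,
    s « 1 means the coefficients are optimistic and would need shrinking).
    A deviance-based heuristic (model χ² − df)/χ² is reported as cross-check.
    Non-finite refits are dropped; more than 20% dropped is an error.
    """
    if n_bootstrap < 50:
        raise ValidationError(f"n_bootstrap: must be >= 50, got {n_bootstrap}")
    x, y = _design(frame, model.predictors, outcome)
    design = sm.add_constant(x, has_constant="add")
    rng = np.random.default_rng(seed)
    n = len(y)
    slopes = []
    dropped = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):
            dropped += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res_b = sm.GLM(yb, design[idx], family=sm.families.Binomial()).fit(
                    tol=IRLS_TOL, maxiter=IRLS_MAXITER
                )
            params_b = np.asarray(res_b.params)
            if not np.all(np.isfinite(params_b)):
                dropped += 1
                continue
            slope = _calibration_slope_raw(design @ params_b, y)
            if not math.isfinite(slope):
                dropped += 1
                continue
            slopes.append(slope)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            dropped += 1
    if dropped > 0.2 * n_bootstrap:
        raise FitError(
            f"shrinkage_factor: {dropped}/{n_bootstrap} bootstrap refits dropped (> 20%)"
        )
    slopes_arr = np.array(slopes)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            tol=IRLS_TOL, maxiter=IRLS_MAXITER
        )
    chi2 = float(res.null_deviance - res.deviance)
    df = x.shape[1]
    heuristic = (chi2 - df) / chi2 if chi2 > 0 else float("nan")

    return ShrinkageResult(
        factor=float(slopes_arr.mean()),
        ci_low=float(np.percentile(slopes_arr, 2.5)),
        ci_high=float(np.percentile(slopes_arr, 97.5)),
        heuristic=heuristic,
        n_bootstrap=n_bootstrap,
        n_dropped=dropped,
    )


# --------------------------------------------------------------------------
# score conversion
# --------------------------------------------------------------------------

class ZeroWeightWarning(UserWarning):
    """A coefficient rounded to 0: the predictor contributes nothing to the score."""


def _round_half_away(value: float) -> int:
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def convert_to_cpr(model: "PrognosticModel | Sequence[float]") -> tuple[int, ...]:
    """Integer score weights: nearest-integer rounding of each raw coefficient.

    Ties round away from zero.  A coefficient rounding to 0 triggers a
    ZeroWeightWarning — the predictor would then not contribute to the score.
    """
    coefs = model.coefficients if isinstance(model, PrognosticModel) else np.asarray(model, float)
    weights = tuple(_round_half_away(float(c)) for c in coefs)
    for w, c in zip(weights, coefs):
        if w == 0:
            warnings.warn(
                f"coefficient {c:.3g} rounds to weight 0; predictor drops out of the score",
                ZeroWeightWarning,
                stacklevel=2,
            )
    return weights


def score(record, weights: Sequence[int]) -> int:
    """Integer score of one complete record: sum of weights over positive predictors."""
    if isinstance(record, (pd.Series, dict)):
        values = [record[p] for p in PREDICTORS]
    else:
        values = list(record)
    if len(values) != len(weights):
        raise ValidationError(f"score: expected {len(weights)} predictor values")
    out = 0
    for v, w in zip(values, weights):
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError("score: record has a missing predictor; scores need complete cases")
        if v not in (0, 1):
            raise ValidationError(f"score: predictor values must be 0/1, got {v!r}")
        out += int(v) * int(w)
    return out


def score_frame(frame: pd.DataFrame, weights: Sequence[int]) -> pd.Series:
    """Vectorized scoring of a coded frame; raises if any predictor is missing."""
    for p in PREDICTORS:
        if frame[p].isna().any():
            raise ValidationError(f"score_frame: column {p!r} has missing values")
    w = np.asarray(weights, int)
    return pd.Series(frame[list(PREDICTORS)].to_numpy(dtype=int) @ w, index=frame.index, name="score")


# --------------------------------------------------------------------------
# score model with study-level random intercept
# --------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """Logistic model in the integer score with a normal study-level intercept.

    ``alpha`` is the log-odds at score 0 for an average study, ``gamma`` the
    log-odds ratio per score point, ``sigma_u`` the between-study intercept
    SD.  ``covariance`` is the 2x2 Wald covariance of (alpha, gamma); None
    when the model was constructed from published parameters rather than fit.
    """

    alpha: float
    gamma: float
    sigma_u: float = 0.0
    covariance: Optional[np.ndarray] = None
    n_used: int = 0
    n_events: int = 0
    loglik: float = float("nan")

    @property
    def per_point_or(self) -> float:
        return float(np.exp(self.gamma))

    def linear_predictor(self, scores) -> np.ndarray:
        return self.alpha + self.gamma * np.asarray(scores, float)

    def eta_ci(self, k: int) -> tuple[float, float, float]:
        """Wald point and 95% CI of the conditional log-odds at score k."""
        eta = self.alpha + self.gamma * k
        if self.covariance is None:
            return eta, float("nan"), float("nan")
        var = (
            self.covariance[0, 0]
            + k * k * self.covariance[1, 1]
            + 2 * k * self.covariance[0, 1]
        )
        half = Z95 * math.sqrt(max(var, 0.0))
        return eta, eta - half, eta + half

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "per_point_or": self.per_point_or,
            "sigma_u": self.sigma_u,
            "covariance": None
            if self.covariance is None
            else [[float(v) for v in row] for row in self.covariance],
            "n_used": self.n_used,
            "n_events": self.n_events,
            "loglik": None if math.isnan(self.loglik) else self.loglik,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        return cls(
            alpha=float(d["alpha"]),
            gamma=float(d["gamma"]),
            sigma_u=float(d.get("sigma_u", 0.0)),
            covariance=None if d.get("covariance") is None else np.array(d["covariance"]),
            n_used=int(d.get("n_used", 0)),
            n_events=int(d.get("n_events", 0)),
            loglik=float("nan") if d.get("loglik") is None else float(d["loglik"]),
        )


def _cluster_loglik(y, s, a, g, sigma, nodes, weights):
    """Adaptive Gauss–Hermite log-integral for one study's outcome vector."""
    eta0 = a + g * s
    # Newton for the mode of h(u) = sum loglik_i(u) - u^2/(2 sigma^2)
    u = 0.0
    for _ in range(50):
        p = expit(eta0 + u)
        grad = float(np.sum(y - p)) - u / sigma**2
        hess = -float(np.sum(p * (1 - p))) - 1 / sigma**2
        step = grad / hess
        u -= step
        if abs(step) < 1e-10:
            break
    p = expit(eta0 + u)
    hess = -float(np.sum(p * (1 - p))) - 1 / sigma**2
    tau = 1.0 / math.sqrt(-hess)
    uk = u + math.sqrt(2.0) * tau * nodes                     # quadrature abscissae
    eta = eta0[None, :] + uk[:, None]
    # Bernoulli log-likelihood, stable: y*eta - log1p(exp(eta))
    ll = np.sum(y[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
    log_integrand = ll - uk**2 / (2 * sigma**2)
    log_terms = np.log(weights) + nodes**2 + log_integrand
    m = log_terms.max()
    integral = math.log(np.sum(np.exp(log_terms - m))) + m + math.log(math.sqrt(2.0) * tau)
    return integral - math.log(sigma * math.sqrt(2 * math.pi))


def _glmm_negloglik(theta, y_by_study, s_by_study, nodes, weights):
    a, g, sigma = theta
    if sigma < 1e-6:
        sigma = 1e-6
    return -sum(
        _cluster_loglik(y, s, a, g, sigma, nodes, weights)
        for y, s in zip(y_by_study, s_by_study)
    )


def fit_score_model(
    scores,
    outcomes,
    study_labels=None,
    sigma_u: Optional[float] = None,
    n_quad: int = 15,
) -> ScoreModel:
    """Fit the score-only logistic model, with study-level random intercept.

    With no study labels (or a single study), or with ``sigma_u=0`` fixed,
    this is an ordinary logistic regression.  Otherwise the marginal
    likelihood over a normal random intercept is maximized with adaptive
    Gauss–Hermite quadrature (``n_quad`` nodes per study); ``sigma_u=None``
    estimates the between-study SD, a positive value fixes it.
    """
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    if s.shape != y.shape:
        raise ValidationError("fit_score_model: scores and outcomes must align")
    if np.unique(s).size < 2:
        raise FitError("fit_score_model: need at least two distinct score values")
    if y.sum() in (0, len(y)):
        raise FitError("fit_score_model: need at least one event and one non-event")

    labels = None if study_labels is None else np.asarray(study_labels)
    single_study = labels is None or np.unique(labels).size < 2

    if single_study or (sigma_u is not None and sigma_u == 0.0):
        design = sm.add_constant(s, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=IRLS_TOL, maxiter=IRLS_MAXITER
            )
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            raise FitError("fit_score_model: non-finite estimates")
        return ScoreModel(
            alpha=float(params[0]),
            gamma=float(params[1]),
            sigma_u=0.0,
            covariance=np.asarray(res.cov_params()),
            n_used=len(y),
            n_events=int(y.sum()),
            loglik=float(res.llf),
        )

    groups = [labels == lab for lab in np.unique(labels)]
    y_by = [y[g] for g in groups]
    s_by = [s[g] for g in groups]
    nodes, weights = hermgauss(n_quad)

    # start from the pooled fixed-effect fit
    pooled = fit_score_model(s, y, study_labels=None)
    estimate_sigma = sigma_u is None
    sigma0 = 0.3 if estimate_sigma else float(sigma_u)

    if estimate_sigma:
        x0 = np.array([pooled.alpha, pooled.gamma, sigma0])
        bounds = [(None, None), (None, None), (1e-6, 5.0)]
        obj = lambda th: _glmm_negloglik(th, y_by, s_by, nodes, weights)
    else:
        x0 = np.array([pooled.alpha, pooled.gamma])
        bounds = [(None, None), (None, None)]
        obj = lambda th: _glmm_negloglik((th[0], th[1], sigma0), y_by, s_by, nodes, weights)

    opt = minimize(obj, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 200})
    if not opt.success and "ABNORMAL" in str(opt.message).upper():
        raise FitError(f"fit_score_model: quadrature ML did not converge: {opt.message}")

    a_hat, g_hat = float(opt.x[0]), float(opt.x[1])
    sig_hat = float(opt.x[2]) if estimate_sigma else sigma0
    if sig_hat <= 2e-6:
        sig_hat = 0.0

    # Wald covariance of (alpha, gamma) from the numerical Hessian at sigma fixed
    def nll_fixed(th):
        return _glmm_negloglik((th[0], th[1], max(sig_hat, 1e-6)), y_by, s_by, nodes, weights)

    hess = approx_hess(np.array([a_hat, g_hat]), nll_fixed)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise FitError("fit_score_model: singular Hessian, no Wald covariance") from exc

    return ScoreModel(
        alpha=a_hat,
        gamma=g_hat,
        sigma_u=sig_hat,
        covariance=cov,
        n_used=len(y),
        n_events=int(y.sum()),
        loglik=float(-opt.fun),
    )


# --------------------------------------------------------------------------
# population-average (marginal) risks
# --------------------------------------------------------------------------

def marginal_probability(eta, sigma_u: float, n_nodes: int = 40) -> float:
    """∫ inverse-logit(eta + u) dN(u; 0, σ_u²): Gauss–Hermite marginalization."""
    if sigma_u < 0:
        raise ValidationError(f"sigma_u: must be >= 0, got {sigma_u}")
    if sigma_u == 0:
        return float(expit(eta))
    nodes, weights = hermgauss(n_nodes)
    return float(np.sum(weights * expit(eta + math.sqrt(2.0) * sigma_u * nodes)) / math.sqrt(math.pi))


def attenuated_probability(eta, sigma_u: float) -> float:
    """Analytic approximation: inverse-logit(eta / sqrt(1 + 0.346 σ_u²))."""
    return float(expit(np.asarray(eta, float) / math.sqrt(1.0 + 0.346 * sigma_u**2)))


@dataclass
class RiskEstimate:
    probability: float
    ci_low: float
    ci_high: float


def population_average_risk(
    score_model: ScoreModel,
    k: int,
    n_nodes: int = 40,
    ci_method: str = "marginalize",
    max_score: Optional[int] = None,
) -> RiskEstimate:
    """Population-average probability of ulcer at score k with 95% CI.

    The point estimate marginalizes the conditional probability over the
    study-level intercept distribution.  The CI applies the same
    marginalization to the Wald CI endpoints of the conditional log-odds at
    score k (``ci_method="marginalize"``); a delta-method interval on the
    marginal scale is available with ``ci_method="delta"``.
    """
    if k < 0 or (max_score is not None and k > max_score):
        raise ValidationError(f"score k={k} outside the score range")
    if ci_method not in ("marginalize", "delta"):
        raise ValidationError(f"ci_method: unknown method {ci_method!r}")
    eta, lo, hi = score_model.eta_ci(k)
    p = marginal_probability(eta, score_model.sigma_u, n_nodes)
    if score_model.covariance is None:
        return RiskEstimate(p, float("nan"), float("nan"))
    if ci_method == "marginalize":
        return RiskEstimate(
            p,
            marginal_probability(lo, score_model.sigma_u, n_nodes),
            marginal_probability(hi, score_model.sigma_u, n_nodes),
        )
    # delta method: dp/deta marginalized, normal interval on the probability
    sigma = score_model.sigma_u
    if sigma == 0:
        deriv = float(expit(eta) * (1 - expit(eta)))
    else:
        nodes, weights = hermgauss(n_nodes)
        pe = expit(eta + math.sqrt(2.0) * sigma * nodes)
        deriv = float(np.sum(weights * pe * (1 - pe)) / math.sqrt(math.pi))
    half_eta = (hi - lo) / 2.0
    half = deriv * half_eta
    return RiskEstimate(p, max(p - half, 0.0), min(p + half, 1.0))


def build_risk_table(
    score_model: ScoreModel,
    scores,
    score_range: Optional[Sequence[int]] = None,
    n_nodes: int = 40,
) -> pd.DataFrame:
    """Per-score table: participant count, marginal risk and 95% CI.

    ``score_range`` defaults to 0..max(observed scores).  With a positive
    per-point log-odds ratio the probabilities are strictly increasing.
    """
    s = np.asarray(scores, int)
    if score_range is None:
        score_range = range(0, int(s.max()) + 1)
    rows = []
    for k in score_range:
        est = population_average_risk(score_model, int(k), n_nodes=n_nodes)
        rows.append(
            {
                "score": int(k),
                "n": int((s == k).sum()),
                "probability": est.probability,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the assembled rule
# --------------------------------------------------------------------------

@dataclass
class CPRule:
    """Integer clinical prediction rule: weights, score model, risk table."""

    weights: tuple
    score_model: ScoreModel
    risk_table: pd.DataFrame
    predictors: tuple = PREDICTORS

    @property
    def max_score(self) -> int:
        return int(sum(self.weights))

    def predicted_risk(self, scores) -> np.ndarray:
        """Map integer scores to the rule's table risks."""
        lookup = dict(zip(self.risk_table["score"], self.risk_table["probability"]))
        s = np.asarray(scores, int)
        missing = set(np.unique(s)) - set(lookup)
        if missing:
            raise ValidationError(f"predicted_risk: scores {sorted(missing)} not in the risk table")
        return np.array([lookup[int(v)] for v in s])

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "weights": {p: int(w) for p, w in zip(self.predictors, self.weights)},
            "score_range": [0, self.max_score],
            "score_model": self.score_model.to_dict(),
            "risk_table": self.risk_table.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def risk_table_csv(self, path) -> None:
        self.risk_table.to_csv(path, index=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CPRule":
        predictors = tuple(d["predictors"])
        return cls(
            weights=tuple(d["weights"][p] for p in predictors),
            score_model=ScoreModel.from_dict(d["score_model"]),
            risk_table=pd.DataFrame(d["risk_table"]),
            predictors=predictors,
        )

    @classmethod
    def from_json(cls, path) -> "CPRule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def develop_cpr(
    frame: pd.DataFrame,
    study_labels: Optional[str] = "study_label",
    sigma_u: Optional[float] = None,
    n_quad: int = 15,
) -> tuple[PrognosticModel, CPRule]:
    """Full development pass on a complete-case coded frame.

    Fits the pooled prognostic model, converts it to integer weights, refits
    the score-only model (with study-level random intercept when several
    studies are present) and tabulates marginal per-score risks.
    """
    model = fit_logistic(frame)
    weights = convert_to_cpr(model)
    scores = score_frame(frame, weights)
    labels = frame[study_labels] if study_labels and study_labels in frame.columns else None
    score_model = fit_score_model(
        scores, frame[OUTCOME].to_numpy(dtype=float), study_labels=labels,
        sigma_u=sigma_u, n_quad=n_quad,
    )
    table = build_risk_table(score_model, scores, score_range=range(0, int(sum(weights)) + 1))
    return model, CPRule(weights=weights, score_model=score_model, risk_table=table)


def score_model_from_published(
    baseline_risk: float, per_point_or: float, sigma_u: float = 0.0
) -> ScoreModel:
    """Score model constructed from a published baseline risk and per-point OR."""
    if not 0 < baseline_risk < 1:
        raise ValidationError(f"baseline_risk: must lie in (0,1), got {baseline_risk}")
    if per_point_or <= 0:
        raise ValidationError(f"per_point_or: must be positive, got {per_point_or}")
    return ScoreModel(
        alpha=float(logit(baseline_risk)), gamma=float(np.log(per_point_or)), sigma_u=sigma_u
    )
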