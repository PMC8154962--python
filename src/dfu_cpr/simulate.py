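"""Synthetic multi-cohort individual-participant data.

The source cohorts (four development studies plus one validation register)
are not public, so every downstream stage is exercised on simulated data
with the same statistical structure: per-study sample sizes, marginal
prevalences of the three binary predictors, and 2-year ulcer outcome rates;
optionally a logistic outcome model with a study-level random intercept
(between-study baseline-risk heterogeneity on the log-odds scale).

Predictors are drawn through a Gaussian copula so a pairwise correlation can
be switched on, but the default is independence: only marginal prevalences
are known for the real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .exceptions import ValidationError

#: fraction of participants with positive history whose history includes an
#: amputation (the cohorts report only the combined ulcer-or-amputation
#: prevalence; the split is cosmetic — analysis uses the combined flag)
AMPUTATION_SHARE = 0.2


@dataclass(frozen=True)
class LogisticOutcome:
    """Conditional outcome model: logit(p) = intercept + b·x + study effect."""

    intercept: float
    coef_mono: float
    coef_pulse: float
    coef_hist: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.coef_mono, self.coef_pulse, self.coef_hist])


@dataclass(frozen=True)
class MarginalRate:
    """Outcome drawn Bernoulli at a fixed marginal rate, ignoring predictors."""

    rate: float


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort study."""

    study_label: str
    n: int
    prev_mono: float
    prev_pulse: float
    prev_hist: float
    outcome_model: "LogisticOutcome | MarginalRate"
    study_intercept_sd: float = 0.0
    missing_rate: float = 0.0
    predictor_corr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if int(self.n) < 1:
            raise ValidationError(f"n: must be >= 1, got {self.n}")
        for name in ("prev_mono", "prev_pulse", "prev_hist", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: proportion must lie in [0,1], got {v}")
        if isinstance(self.outcome_model, MarginalRate):
            if not 0.0 <= self.outcome_model.rate <= 1.0:
                raise ValidationError(
                    f"outcome_model.rate: proportion must lie in [0,1], got {self.outcome_model.rate}"
                )
        if self.study_intercept_sd < 0:
            raise ValidationError(
                f"study_intercept_sd: must be >= 0, got {self.study_intercept_sd}"
            )
        if not -0.99 <= self.predictor_corr <= 0.99:
            raise ValidationError(
                f"predictor_corr: must lie in [-0.99, 0.99], got {self.predictor_corr}"
            )


def _bernoulli_from_copula(rng: np.random.Generator, n: int, prevs, corr: float) -> np.ndarray:
    """Draw correlated Bernoulli columns via an equicorrelated Gaussian latent."""
    k = len(prevs)
    z = rng.standard_normal((n, k))
    if corr != 0.0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(abs(corr)) * np.sign(corr) * shared + np.sqrt(1 - abs(corr)) * z
    thresholds = norm.ppf(prevs)
    return (z < thresholds).astype(np.int64)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort as a frame of participant records.

    Predictors are Bernoulli at the spec prevalences (independent by default);
    the outcome is Bernoulli either at a fixed marginal rate or from the
    logistic model with a study-level intercept drawn once per cohort from
    N(0, study_intercept_sd²).  Missingness is injected completely at random,
    per analysis field, at ``missing_rate``.  Identical spec (including seed)
    gives bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n)
    x = _bernoulli_from_copula(
        rng, n, [spec.prev_mono, spec.prev_pulse, spec.prev_hist], spec.predictor_corr
    )
    mono, pulse, hist = x[:, 0], x[:, 1], x[:, 2]

    # study intercept: one draw per cohort, even when the marginal model makes
    # it irrelevant, so the rng stream does not depend on the model type
    u = rng.standard_normal() * spec.study_intercept_sd
    if isinstance(spec.outcome_model, MarginalRate):
        p = np.full(n, spec.outcome_model.rate)
    else:
        m = spec.outcome_model
        eta = m.intercept + u + x @ m.coefficients
        p = expit(eta)
    outcome = (rng.random(n) < p).astype(np.int64)

    # split combined history into components (ulcer dominant; see methods note)
    amput = np.where(hist == 1, (rng.random(n) < AMPUTATION_SHARE).astype(np.int64), 0)

    frame = pd.DataFrame(
        {
            "study_label": spec.study_label,
            "mono_insensate": pd.array(mono, dtype="Int64"),
            "pulses_absent": pd.array(pulse, dtype="Int64"),
            "prior_ulcer": pd.array(hist, dtype="Int64"),
            "prior_amputation": pd.array(amput, dtype="Int64"),
            "ulcer_2yr": pd.array(outcome, dtype="Int64"),
        }
    )
    if spec.missing_rate > 0:
        miss = rng.random((n, 4)) < spec.missing_rate
        frame.loc[miss[:, 0], "mono_insensate"] = pd.NA
        frame.loc[miss[:, 1], "pulses_absent"] = pd.NA
        # history goes missing as a unit: both components unobserved
        frame.loc[miss[:, 2], ["prior_ulcer", "prior_amputation"]] = pd.NA
        frame.loc[miss[:, 3], "ulcer_2yr"] = pd.NA
    return frame


# --- study conditions of the pooled analysis ------------------------------

#: four development cohorts: complete-data size, predictor prevalences and
#: 2-year ulcer rate (two UK community cohorts, one Portuguese and one US
#: secondary-care foot clinic)
DEVELOPMENT_COHORTS: tuple[dict, ...] = (
    dict(study_label="community-uk-1", n=6478, prev_mono=0.194, prev_pulse=0.296, prev_hist=0.047, rate=0.044),
    dict(study_label="community-uk-2", n=1175, prev_mono=0.223, prev_pulse=0.188, prev_hist=0.072, rate=0.019),
    dict(study_label="clinic-pt", n=360, prev_mono=0.461, prev_pulse=0.203, prev_hist=0.381, rate=0.144),
    dict(study_label="clinic-us", n=242, prev_mono=0.746, prev_pulse=0.145, prev_hist=0.714, rate=0.278),
)

#: external validation register (UK electronic health register)
VALIDATION_COHORT: dict = dict(
    study_label="register-uk", n=3324, prev_mono=0.207, prev_pulse=0.140, prev_hist=0.057, rate=0.039
)

#: pooled development-model parameters (log-odds): baseline risk 2.2% and the
#: three predictor coefficients
POOLED_MODEL = LogisticOutcome(
    intercept=float(logit(0.022)), coef_mono=1.11, coef_pulse=0.70, coef_hist=1.95
)

#: score-model parameters of the published rule: baseline risk 2.4%, odds
#: ratio 2.57 per score point
SCORE_ALPHA = float(logit(0.024))
SCORE_GAMMA = float(np.log(2.57))

#: development-data score distribution (scores 0..4)
SCORE_COUNTS = np.array([4646, 2406, 676, 358, 169])

#: default between-study intercept SD for logistic scenarios (stand-in; the
#: real between-study variance is not published)
DEFAULT_SIGMA_U = 0.3


def development_specs(
    seed: int,
    outcome: str = "marginal",
    sigma_u: float = DEFAULT_SIGMA_U,
    missing_rate: float = 0.0,
) -> list[CohortSpec]:
    """CohortSpecs for the four development cohorts.

    ``outcome="marginal"`` reproduces each study's observed 2-year ulcer rate;
    ``outcome="logistic"`` draws outcomes from the pooled three-predictor
    model with a per-study random intercept of SD ``sigma_u``.
    """
    if outcome not in ("marginal", "logistic"):
        raise ValidationError(f"outcome: expected 'marginal' or 'logistic', got {outcome!r}")
    ss = np.random.SeedSequence(seed).spawn(len(DEVELOPMENT_COHORTS))
    specs = []
    for row, sub in zip(DEVELOPMENT_COHORTS, ss):
        if outcome == "marginal":
            model: LogisticOutcome | MarginalRate = MarginalRate(row["rate"])
            sd = 0.0
        else:
            model = POOLED_MODEL
            sd = sigma_u
        specs.append(
            CohortSpec(
                study_label=row["study_label"],
                n=row["n"],
                prev_mono=row["prev_mono"],
                prev_pulse=row["prev_pulse"],
                prev_hist=row["prev_hist"],
                outcome_model=model,
                study_intercept_sd=sd,
                missing_rate=missing_rate,
                seed=int(sub.generate_state(1)[0] % (2**31)),
            )
        )
    return specs


def simulate_development_suite(seed: int, **kwargs) -> dict[str, pd.DataFrame]:
    """Generate the four development cohorts; keys are the study labels."""
    return {s.study_label: simulate_cohort(s) for s in development_specs(seed, **kwargs)}


def pool_cohorts(cohorts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-study frames into one pooled IPD frame."""
    return pd.concat(cohorts.values(), ignore_index=True)


def simulate_score_register(
    n: int,
    seed: int,
    alpha: float = SCORE_ALPHA,
    gamma: float = SCORE_GAMMA,
    score_probs: Optional[Sequence[float]] = None,
    sigma_u: float = 0.0,
) -> pd.DataFrame:
    """Simulate a register of (score, outcome) pairs from a score model.

    Scores are drawn from ``score_probs`` (default: the development score
    distribution) and outcomes are Bernoulli at inverse-logit(alpha +
    gamma·score + u) with a single register-level intercept u ~ N(0, σ_u²).
    """
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    probs = (
        SCORE_COUNTS / SCORE_COUNTS.sum() if score_probs is None else np.asarray(score_probs, float)
    )
    if not np.isclose(probs.sum(), 1.0):
        raise ValidationError("score_probs: must sum to 1")
    rng = np.random.default_rng(seed)
    scores = rng.choice(len(probs), size=n, p=probs)
    u = rng.standard_normal() * sigma_u
    p = expit(alpha + gamma * scores + u)
    outcome = (rng.random(n) < p).astype(np.int64)
    return pd.DataFrame({"score": scores, "ulcer_2yr": outcome})


# --- YAML scenarios -------------------------------------------------------

def spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "study_label": spec.study_label,
        "n": spec.n,
        "prev_mono": spec.prev_mono,
        "prev_pulse": spec.prev_pulse,
        "prev_hist": spec.prev_hist,
        "study_intercept_sd": spec.study_intercept_sd,
        "missing_rate": spec.missing_rate,
        "predictor_corr": spec.predictor_corr,
        "seed": spec.seed,
    }
    if isinstance(spec.outcome_model, MarginalRate):
        d["outcome_model"] = {"marginal_rate": spec.outcome_model.rate}
    else:
        m = spec.outcome_model
        d["outcome_model"] = {
            "logistic": {
                "intercept": m.intercept,
                "coef_mono": m.coef_mono,
                "coef_pulse": m.coef_pulse,
                "coef_hist": m.coef_hist,
            }
        }
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    om = d.get("outcome_model")
    if not isinstance(om, dict) or len(om) != 1:
        raise ValidationError("outcome_model: expected {'marginal_rate': p} or {'logistic': {...}}")
    if "marginal_rate" in om:
        model: LogisticOutcome | MarginalRate = MarginalRate(float(om["marginal_rate"]))
    elif "logistic" in om:
        model = LogisticOutcome(**{k: float(v) for k, v in om["logistic"].items()})
    else:
        raise ValidationError(f"outcome_model: unknown form {list(om)!r}")
    keys = (
        "study_label", "n", "prev_mono", "prev_pulse", "prev_hist",
        "study_intercept_sd", "missing_rate", "predictor_corr", "seed",
    )
    kwargs = {k: d[k] for k in keys if k in d}
    return CohortSpec(outcome_model=model, **kwargs)


def load_scenario(path) -> list[CohortSpec]:
    """Read a YAML scenario file: a list of CohortSpec mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("scenario file: expected a YAML list of cohort specs")
    return [spec_from_dict(d) for d in raw]


def save_scenario(specs: Sequence[CohortSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([spec_to_dict(s) for s in specs], fh, sort_keys=False)


def reseed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of a spec with a new seed (convenience for replicate studies)."""
    return replace(spec, seed=seed)
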