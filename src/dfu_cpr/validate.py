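"""External validation: discrimination, calibration and grouped calibration data.

Discrimination is the C-statistic (probability that a randomly chosen event
case outranks a randomly chosen non-event case, ties counted half) with a
DeLong confidence interval.  Calibration is summarized by the calibration
slope (coefficient of the model's linear predictor refitted on the
validation outcomes; 1 is ideal) and calibration-in-the-large (intercept of
a refit with the linear predictor as a fixed offset; 0 is ideal), plus
per-score groups with exact binomial intervals for the calibration plot.

Raw integer scores carry no probability scale, so calibration of a score
rule is always computed on the score model's linear predictor alpha +
gamma*score, never on the scores themselves.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta, norm, rankdata

from .develop import IRLS_MAXITER, IRLS_TOL, CPRule, ScoreModel, score_frame
from .exceptions import FitError, ValidationError

log = logging.getLogger(__name__)

Z95 = norm.ppf(0.975)


def _check_outcomes(y: np.ndarray) -> None:
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("outcomes must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("need at least one event and one non-event")


@dataclass
class CStatResult:
    value: float
    ci_low: float
    ci_high: float
    se: float

    def to_dict(self) -> dict:
        return {"value": self.value, "ci_low": self.ci_low, "ci_high": self.ci_high, "se": self.se}


def c_statistic(scores, outcomes, ci: bool = True) -> CStatResult:
    """Tie-corrected rank C-statistic with DeLong 95% CI.

    Exact over all event x non-event pairs via midranks (Mann–Whitney); the
    variance uses the DeLong placement decomposition, which is deterministic
    (no resampling).
    """
    x = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    if x.shape != y.shape:
        raise ValidationError("scores and outcomes must align")
    _check_outcomes(y)
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-event placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-non-event placements
    auc = float(v10.mean())
    if not ci or m < 2 or n < 2:
        return CStatResult(auc, float("nan"), float("nan"), float("nan"))
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = math.sqrt(var)
    return CStatResult(
        auc, max(auc - Z95 * se, 0.0), min(auc + Z95 * se, 1.0), se
    )


@dataclass
class CalibrationResult:
    slope: float
    slope_ci: tuple
    itl: float                       # calibration-in-the-large (log-odds)
    itl_ci: tuple

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "calibration_in_the_large": self.itl,
            "itl_ci": list(self.itl_ci),
        }


def calibration_metrics(linear_predictor, outcomes) -> CalibrationResult:
    """Calibration slope and calibration-in-the-large with Wald 95% CIs."""
    lp = np.asarray(linear_predictor, float)
    y = np.asarray(outcomes, int)
    if lp.shape != y.shape:
        raise ValidationError("linear predictor and outcomes must align")
    if not np.all(np.isfinite(lp)):
        raise ValidationError("linear predictor has non-finite values")
    _check_outcomes(y)
    if np.unique(lp).size < 2:
        raise ValidationError("constant linear predictor: calibration slope unidentifiable")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slope_res = sm.GLM(
            y, sm.add_constant(lp, has_constant="add"), family=sm.families.Binomial()
        ).fit(tol=IRLS_TOL, maxiter=IRLS_MAXITER)
        itl_res = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
        ).fit(tol=IRLS_TOL, maxiter=IRLS_MAXITER)
    b = float(slope_res.params[1])
    b_se = float(slope_res.bse[1])
    a = float(itl_res.params[0])
    a_se = float(itl_res.bse[0])
    if not all(map(math.isfinite, (b, b_se, a, a_se))):
        raise FitError("calibration refit produced non-finite estimates")
    return CalibrationResult(
        slope=b,
        slope_ci=(b - Z95 * b_se, b + Z95 * b_se),
        itl=a,
        itl_ci=(a - Z95 * a_se, a + Z95 * a_se),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def calibration_groups(scores, outcomes, risk_table: pd.DataFrame) -> pd.DataFrame:
    """Per-score observed vs predicted rows for the calibration plot.

    One row per score level of the risk table that is actually observed:
    count, observed event proportion with exact (Clopper–Pearson) 95% CI, and
    the table's predicted probability.  Score levels with no participants are
    omitted (logged); scores absent from the table are an error.
    """
    s = np.asarray(scores, int)
    y = np.asarray(outcomes, int)
    if s.shape != y.shape:
        raise ValidationError("scores and outcomes must align")
    table_scores = set(int(v) for v in risk_table["score"])
    missing = set(np.unique(s)) - table_scores
    if missing:
        raise ValidationError(f"scores {sorted(missing)} not present in the risk table")
    predicted = dict(zip(risk_table["score"].astype(int), risk_table["probability"]))
    rows = []
    for k in sorted(table_scores):
        mask = s == k
        n_k = int(mask.sum())
        if n_k == 0:
            log.info("calibration_groups: no participants at score %d; row omitted", k)
            continue
        events = int(y[mask].sum())
        lo, hi = clopper_pearson(events, n_k)
        rows.append(
            {
                "score": k,
                "n": n_k,
                "observed": events / n_k,
                "ci_low": lo,
                "ci_high": hi,
                "predicted": predicted[k],
            }
        )
    return pd.DataFrame(rows)


def roc_points(scores, outcomes) -> pd.DataFrame:
    """ROC points (1-specificity, sensitivity), one per threshold between
    distinct score values, anchored at (0,0) and (1,1).

    For discrete scores the trapezoidal area under these points equals the
    tie-corrected C-statistic.
    """
    x = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    if x.shape != y.shape:
        raise ValidationError("scores and outcomes must align")
    _check_outcomes(y)
    m = y.sum()
    n = len(y) - m
    fpr = [0.0]
    tpr = [0.0]
    for v in sorted(np.unique(x))[::-1]:          # descending thresholds
        positive = x >= v
        tpr.append(float((positive & (y == 1)).sum() / m))
        fpr.append(float((positive & (y == 0)).sum() / n))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_auc(points: pd.DataFrame) -> float:
    """Trapezoidal area under an ROC point set."""
    return float(np.trapezoid(points["tpr"], points["fpr"]))


@dataclass
class ValidationReport:
    """Bundle of validation results for one target dataset."""

    c_statistic: CStatResult
    calibration: CalibrationResult
    groups: Optional[pd.DataFrame]
    n_used: int
    n_events: int
    c_statistic_model: Optional[CStatResult] = None    # full prognostic model, if compared

    def to_dict(self) -> dict:
        d = {
            "c_statistic": self.c_statistic.to_dict(),
            "calibration": self.calibration.to_dict(),
            "groups": None if self.groups is None else self.groups.to_dict(orient="records"),
            "n_used": self.n_used,
            "n_events": self.n_events,
        }
        if self.c_statistic_model is not None:
            d["c_statistic_prognostic_model"] = self.c_statistic_model.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def validate_scores(
    score_model: ScoreModel,
    scores,
    outcomes,
    risk_table: Optional[pd.DataFrame] = None,
) -> ValidationReport:
    """Validate a score rule on new data.

    The calibration refits use the score model's linear predictor
    alpha + gamma*score; discrimination uses the (rank-equivalent) scores.
    """
    s = np.asarray(scores, int)
    y = np.asarray(outcomes, int)
    lp = score_model.linear_predictor(s)
    report = ValidationReport(
        c_statistic=c_statistic(s, y),
        calibration=calibration_metrics(lp, y),
        groups=None if risk_table is None else calibration_groups(s, y, risk_table),
        n_used=len(y),
        n_events=int(y.sum()),
    )
    return report


def validate_cpr(cpr: CPRule, frame: pd.DataFrame, prognostic_lp=None) -> ValidationReport:
    """Validate a fitted rule on a complete-case coded frame.

    When ``prognostic_lp`` (the full model's linear predictor per record) is
    supplied, the full model's C-statistic is reported alongside the rule's,
    quantifying the discrimination lost by the integer simplification.
    """
    scores = score_frame(frame, cpr.weights)
    y = frame["ulcer_2yr"].to_numpy(dtype=int)
    report = validate_scores(cpr.score_model, scores, y, risk_table=cpr.risk_table)
    if prognostic_lp is not None:
        report.c_statistic_model = c_statistic(np.asarray(prognostic_lp, float), y)
    return report


def plot_calibration(groups: pd.DataFrame, path) -> None:
    """Calibration figure: observed vs predicted per score group, with CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(groups["ci_high"].max(), groups["predicted"].max()) * 1.1
    ax.plot([0, lim], [0, lim], color="0.6", lw=1, label="perfect calibration")
    ax.vlines(groups["predicted"], groups["ci_low"], groups["ci_high"], color="k", lw=1)
    ax.plot(groups["predicted"], groups["observed"], "ko", label="score groups")
    ax.set_xlabel("predicted probability of ulcer by 2 years")
    ax.set_ylabel("observed proportion")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(points: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(points["fpr"], points["tpr"], "k-o", ms=3)
    ax.plot([0, 1], [0, 1], color="0.6", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
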