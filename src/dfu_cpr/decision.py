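"""Net-benefit decision-curve analysis of the prediction rule.

Net benefit at threshold probability p_t weighs true positives against false
positives at the odds of the threshold:

    NB = TP/n - FP/n * p_t / (1 - p_t)

Treat-none has net benefit 0 everywhere; treat-all has net benefit
pi - (1 - pi) * p_t/(1 - p_t) where pi is the event prevalence.  A decision
curve evaluates the rule-guided strategy ("treat if predicted risk >= p_t")
across a grid of thresholds; the referral recommendation is the smallest
score whose table risk, used as a fixed treat/don't-treat cut, is at least
as good as both reference strategies throughout a clinically plausible
threshold range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: default threshold grid: 0.005 to 0.30 in steps of 0.005
DEFAULT_GRID = np.round(np.arange(0.005, 0.300 + 1e-9, 0.005), 10)

#: clinically plausible referral thresholds over which a score cut must
#: dominate both reference strategies (see methods note)
DEFAULT_CLINICAL_RANGE = (0.03, 0.10)


def _check_threshold(p_t: float) -> None:
    if not 0.0 < p_t < 1.0:
        raise ValidationError(f"threshold probability must lie in (0,1), got {p_t}")


def net_benefit(outcomes, treat_flags, p_t: float) -> float:
    """Net benefit of a fixed treatment assignment at threshold p_t."""
    _check_threshold(p_t)
    y = np.asarray(outcomes, int)
    t = np.asarray(treat_flags, bool)
    if y.shape != t.shape:
        raise ValidationError("outcomes and treat_flags must align")
    n = len(y)
    tp = int((t & (y == 1)).sum())
    fp = int((t & (y == 0)).sum())
    return tp / n - (fp / n) * (p_t / (1.0 - p_t))


@dataclass
class DecisionCurve:
    """Net benefit of rule-guided, treat-all and treat-none strategies."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    outcomes: np.ndarray
    risks: np.ndarray

    @property
    def nb_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    @property
    def prevalence(self) -> float:
        return float(self.outcomes.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decision_curve(outcomes, predicted_risks, thresholds=None) -> DecisionCurve:
    """Decision curve: at each grid threshold p_t the rule treats records
    with predicted risk >= p_t (closed lower bound)."""
    y = np.asarray(outcomes, int)
    r = np.asarray(predicted_risks, float)
    if y.shape != r.shape:
        raise ValidationError("outcomes and predicted_risks must align")
    if np.any((r <= 0) | (r >= 1)):
        raise ValidationError("predicted risks must lie strictly in (0,1)")
    grid = DEFAULT_GRID if thresholds is None else np.asarray(thresholds, float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValidationError("threshold grid must be a non-empty 1-d array")
    if np.any((grid <= 0) | (grid >= 1)) or np.any(np.diff(grid) <= 0):
        raise ValidationError("threshold grid must be strictly increasing within (0,1)")
    nb_model = np.array([net_benefit(y, r >= p_t, p_t) for p_t in grid])
    nb_all = np.array([net_benefit(y, np.ones_like(y, bool), p_t) for p_t in grid])
    return DecisionCurve(
        thresholds=grid, nb_model=nb_model, nb_all=nb_all, outcomes=y, risks=r
    )


@dataclass
class Recommendation:
    """Referral recommendation: a score cut and its table risk, or neither."""

    score: Optional[int]
    risk: Optional[float]
    reason: str = ""

    def __bool__(self) -> bool:
        return self.score is not None

    def to_dict(self) -> dict:
        return {"score": self.score, "risk": self.risk, "reason": self.reason}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def recommend_threshold(
    curve: DecisionCurve,
    risk_table: pd.DataFrame,
    clinical_range: Sequence[float] = DEFAULT_CLINICAL_RANGE,
) -> Recommendation:
    """Smallest score whose table risk, used as the treatment cut, has net
    benefit >= treat-all and >= treat-none at every grid threshold within
    ``clinical_range``.

    Returns an explicit no-recommendation result (never raises) when no
    score level dominates throughout the range.
    """
    lo, hi = clinical_range
    in_range = (curve.thresholds >= lo) & (curve.thresholds <= hi)
    if not in_range.any():
        return Recommendation(None, None, "no grid thresholds inside the clinical range")
    grid = curve.thresholds[in_range]
    nb_all = curve.nb_all[in_range]
    tol = 1e-12
    table = risk_table.sort_values("score")
    for k, risk_k in zip(table["score"].astype(int), table["probability"].astype(float)):
        treat = curve.risks >= risk_k - tol
        nb_k = np.array([net_benefit(curve.outcomes, treat, p_t) for p_t in grid])
        if np.all(nb_k >= nb_all - tol) and np.all(nb_k >= -tol):
            return Recommendation(int(k), float(risk_k))
    return Recommendation(
        None, None, "no score cut dominates both reference strategies over the clinical range"
    )


def plot_decision_curve(curve: DecisionCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.nb_model, "k-", label="prediction rule")
    ax.plot(curve.thresholds, curve.nb_all, "-", color="0.5", label="treat all")
    ax.axhline(0.0, color="0.7", lw=1, label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.02, curve.nb_all.min() - 0.01))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
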