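"""Harmonization of heterogeneous cohort data into the three binary predictors.

Contributing cohort studies recorded foot examinations differently: some give
per-site 10 g monofilament results, some a single pre-coded insensitivity flag;
pedal pulses may come as four per-pulse fields (dorsalis pedis and posterior
tibial, each foot) or pre-coded.  This module applies one consistent coding:

* monofilament insensitivity — 1 if the participant was insensate at any
  tested site, 0 if the monofilament was felt at every observed site;
* absent pulses — 1 if any of the four pulses is absent, 0 if all four are
  present;
* previous history — 1 if the participant ever had a foot ulcer or a lower
  extremity amputation, 0 if neither.

All coders use three-valued logic ({0, 1, missing}); analysis proceeds on
complete cases only (no imputation — the source cohorts are 97–98% complete).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

log = logging.getLogger(__name__)

FELT = "felt"
NOT_FELT = "not_felt"
PRESENT = "present"
ABSENT = "absent"

#: predictor/outcome columns a coded analysis frame must carry
ANALYSIS_FIELDS = ("mono_insensate", "pulses_absent", "history", "ulcer_2yr")

#: columns of the cohort CSV interchange format (missing = empty field)
CSV_COLUMNS = (
    "study_label",
    "mono_insensate",
    "pulses_absent",
    "prior_ulcer",
    "prior_amputation",
    "ulcer_2yr",
)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return value is pd.NA or value == ""


def code_monofilament(site_results, strict: bool = False):
    """Code per-site monofilament results into {0, 1, missing}.

    ``site_results`` is a sequence over tested plantar sites with entries
    ``"felt"``, ``"not_felt"`` or missing (None/NaN/empty).  The number of
    sites is not fixed — studies varied in how many they tested.

    Returns 1 if any site was insensate, 0 if every observed site was felt,
    missing if no site was observed.  With ``strict=True`` a participant with
    any unobserved site codes missing unless some site was insensate.
    """
    sites = list(site_results)
    if not sites:
        raise ValidationError("site_results: at least one monofilament site is required")
    statuses = []
    for s in sites:
        if _is_missing(s):
            statuses.append(None)
        elif s == NOT_FELT:
            statuses.append(1)
        elif s == FELT:
            statuses.append(0)
        else:
            raise ValidationError(f"site_results: unrecognized site result {s!r}")
    if any(v == 1 for v in statuses):
        return 1
    if all(v is None for v in statuses):
        return None
    if strict and any(v is None for v in statuses):
        return None
    return 0


def code_pulses(pulse_results):
    """Code the four pedal pulses into {0, 1, missing}.

    Expects exactly four entries (dorsalis pedis and posterior tibial on each
    foot), each ``"present"``, ``"absent"`` or missing.  Returns 1 if any
    pulse is absent, 0 if all four are present, missing if no pulse is absent
    but at least one is unobserved.
    """
    pulses = list(pulse_results)
    if len(pulses) != 4:
        raise ValidationError(
            f"pulse_results: exactly 4 pulses expected, got {len(pulses)}"
        )
    statuses = []
    for p in pulses:
        if _is_missing(p):
            statuses.append(None)
        elif p == ABSENT:
            statuses.append(1)
        elif p == PRESENT:
            statuses.append(0)
        else:
            raise ValidationError(f"pulse_results: unrecognized pulse result {p!r}")
    if any(v == 1 for v in statuses):
        return 1
    if any(v is None for v in statuses):
        return None
    return 0


def code_history(prior_ulcer, prior_amputation):
    """Three-valued OR of previous ulcer and previous amputation.

    1 if either component is 1; 0 if both are 0; missing otherwise (a missing
    component could flip a 0 to a 1, so the OR is unknown).
    """
    u = None if _is_missing(prior_ulcer) else int(prior_ulcer)
    a = None if _is_missing(prior_amputation) else int(prior_amputation)
    for v, name in ((u, "prior_ulcer"), (a, "prior_amputation")):
        if v is not None and v not in (0, 1):
            raise ValidationError(f"{name}: must be 0, 1 or missing, got {v!r}")
    if u == 1 or a == 1:
        return 1
    if u == 0 and a == 0:
        return 0
    return None


def add_history(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the combined ``history`` column from the two component columns."""
    out = frame.copy()
    u = out["prior_ulcer"]
    a = out["prior_amputation"]
    hist = pd.Series(pd.NA, index=out.index, dtype="Int64")
    hist[(u == 1) | (a == 1)] = 1
    hist[(u == 0) & (a == 0)] = 0
    out["history"] = hist
    return out


@dataclass
class ExclusionReport:
    """Accounting of complete-case filtering."""

    n_input: int
    n_retained: int
    missing_counts: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    @property
    def retention(self) -> float:
        return 1.0 if self.n_input == 0 else self.n_retained / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "retention": self.retention,
            "missing_counts": dict(self.missing_counts),
        }


def complete_case_filter(frame: pd.DataFrame):
    """Retain records with all three predictors and the outcome non-missing.

    Returns ``(retained, ExclusionReport)``.  Field values are never altered;
    the retained and excluded rows partition the input.
    """
    for col in ANALYSIS_FIELDS:
        if col not in frame.columns:
            raise ValidationError(f"complete_case_filter: missing column {col!r}")
    if frame.empty:
        return frame.copy(), ExclusionReport(0, 0, {c: 0 for c in ANALYSIS_FIELDS})
    missing = {col: int(frame[col].isna().sum()) for col in ANALYSIS_FIELDS}
    keep = ~frame[list(ANALYSIS_FIELDS)].isna().any(axis=1)
    retained = frame[keep].copy()
    return retained, ExclusionReport(len(frame), len(retained), missing)


# --- CSV dialects ---------------------------------------------------------

RAW_PULSE_COLUMNS = ("pulse_dp_left", "pulse_pt_left", "pulse_dp_right", "pulse_pt_right")


def harmonize_table(frame: pd.DataFrame, dialect: str = "coded") -> pd.DataFrame:
    """Convert a raw cohort table to the coded analysis frame.

    ``dialect="coded"``: expects pre-coded 0/1 columns ``mono_insensate`` and
    ``pulses_absent`` alongside ``prior_ulcer``/``prior_amputation``.
    ``dialect="raw"``: expects per-site columns ``mono_site_1..k`` and the
    four per-pulse columns; these are coded here.
    Both dialects require ``ulcer_2yr`` (already a 2-year binary) and derive
    the combined ``history`` column.
    """
    if dialect not in ("coded", "raw"):
        raise ValidationError(f"unknown CSV dialect {dialect!r}")
    frame = frame.copy()
    if dialect == "raw":
        mono_cols = sorted(c for c in frame.columns if c.startswith("mono_site_"))
        if not mono_cols:
            raise ValidationError("raw dialect: no mono_site_* columns found")
        for col in RAW_PULSE_COLUMNS:
            if col not in frame.columns:
                raise ValidationError(f"raw dialect: missing pulse column {col!r}")
        frame["mono_insensate"] = pd.array(
            [code_monofilament(row) for row in frame[mono_cols].itertuples(index=False)],
            dtype="Int64",
        )
        frame["pulses_absent"] = pd.array(
            [code_pulses(row) for row in frame[list(RAW_PULSE_COLUMNS)].itertuples(index=False)],
            dtype="Int64",
        )
        frame = frame.drop(columns=mono_cols + list(RAW_PULSE_COLUMNS))
    required = ["mono_insensate", "pulses_absent", "prior_ulcer", "prior_amputation", "ulcer_2yr"]
    for col in required:
        if col not in frame.columns:
            raise ValidationError(f"harmonize: missing required column {col!r}")
    for col in required:
        frame[col] = frame[col].astype("Int64")
        bad = frame[col].dropna()
        if not bad.isin((0, 1)).all():
            raise ValidationError(f"harmonize: column {col!r} has values outside {{0,1}}")
    return add_history(frame)


def read_cohort_csv(path, dialect: str = "coded") -> pd.DataFrame:
    """Read a cohort CSV (missing encoded as empty fields) and harmonize it."""
    frame = pd.read_csv(path, dtype={"study_label": str})
    return harmonize_table(frame, dialect=dialect)


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write the interchange columns of a cohort frame; missing as empty fields."""
    cols = [c for c in CSV_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False, na_rep="")
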