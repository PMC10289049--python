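"""Declarative subgroup filters for stratified accuracy analyses.

Named strata cover age bands (<18, 18–59, ≥60 years), sex, fasting status,
TG bands (<400, 150–399, 400–799 mg/dL; half-open), and clinical subgroups:
ASCVD and hypertension (pre-computed diagnosis booleans), kidney disease
(eGFR < 60 mL/min/1.73 m²), diabetes (diagnosis flag OR A1c > 6.5% OR
fasting glucose ≥ 126 mg/dL), inflammation (hsCRP ≥ 2 mg/L) and thyroid
dysfunction (TSH < 0.5 or > 4.5 uIU/mL). Inequality strictness follows the
clinical definitions exactly: A1c and TSH bounds are strict, glucose and
hsCRP bounds are inclusive.

Records missing a covariate required by a stratum are excluded from that
stratum and counted, never silently dropped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UnknownStratumError


@dataclass(frozen=True)
class StratumSelection:
    """Boolean membership mask plus the count excluded for missing data."""

    name: str
    mask: pd.Series
    n_missing: int

    @property
    def n(self) -> int:
        return int(self.mask.sum())


def _num(cohort: pd.DataFrame, col: str) -> pd.Series:
    if col not in cohort.columns:
        return pd.Series(np.nan, index=cohort.index, dtype=float)
    return pd.to_numeric(cohort[col], errors="coerce")


def _band(values: pd.Series, lo: float, hi: float):
    """Half-open band [lo, hi); returns (mask, missing)."""
    missing = values.isna()
    return (values >= lo) & (values < hi) & ~missing, missing


def _categorical(cohort: pd.DataFrame, col: str, value: str):
    if col not in cohort.columns:
        missing = pd.Series(True, index=cohort.index)
        return pd.Series(False, index=cohort.index), missing
    missing = cohort[col].isna()
    return (cohort[col] == value) & ~missing, missing


def _flag(cohort: pd.DataFrame, col: str):
    if col not in cohort.columns:
        missing = pd.Series(True, index=cohort.index)
        return pd.Series(False, index=cohort.index), missing
    missing = cohort[col].isna()
    return cohort[col].fillna(False).astype(bool), missing


def _diabetes(cohort: pd.DataFrame):
    """Diagnosis flag OR A1c > 6.5 OR fasting glucose >= 126; a record is
    'missing' only when none of the three criteria is available."""
    dx, dx_missing = _flag(cohort, "diabetes_dx")
    a1c = _num(cohort, "a1c")
    glu = _num(cohort, "fasting_glucose")
    mask = dx | (a1c > 6.5) | (glu >= 126)
    missing = dx_missing & a1c.isna() & glu.isna()
    return mask & ~missing, missing


def _thyroid(cohort: pd.DataFrame):
    tsh = _num(cohort, "tsh")
    missing = tsh.isna()
    return ((tsh < 0.5) | (tsh > 4.5)) & ~missing, missing


_STRATA = {
    "all": lambda c: (pd.Series(True, index=c.index), pd.Series(False, index=c.index)),
    "age_lt_18": lambda c: _band(_num(c, "age"), 0, 18),
    "age_18_59": lambda c: _band(_num(c, "age"), 18, 60),
    "age_ge_60": lambda c: _band(_num(c, "age"), 60, np.inf),
    "female": lambda c: _categorical(c, "sex", "female"),
    "male": lambda c: _categorical(c, "sex", "male"),
    "fasting": lambda c: _categorical(c, "fasting", "fasting"),
    "non_fasting": lambda c: _categorical(c, "fasting", "non_fasting"),
    "fasting_unknown": lambda c: _categorical(c, "fasting", "unknown"),
    "tg_lt_400": lambda c: _band(_num(c, "tg"), 0, 400),
    "tg_150_399": lambda c: _band(_num(c, "tg"), 150, 400),
    "tg_400_799": lambda c: _band(_num(c, "tg"), 400, 800),
    "ascvd": lambda c: _flag(c, "ascvd"),
    "hypertension": lambda c: _flag(c, "hypertension"),
    "kidney_disease": lambda c: _band(_num(c, "egfr"), -np.inf, 60),
    "diabetes": _diabetes,
    "inflammation": lambda c: _band(_num(c, "hscrp"), 2, np.inf),
    "thyroid_dysfunction": _thyroid,
}

AVAILABLE_STRATA = tuple(_STRATA)


def stratum_selection(cohort: pd.DataFrame, name: str) -> StratumSelection:
    """Evaluate a named stratum predicate; unknown names raise with the list
    of available strata."""
    try:
        predicate = _STRATA[name]
    except KeyError:
        raise UnknownStratumError(name, AVAILABLE_STRATA) from None
    mask, missing = predicate(cohort)
    return StratumSelection(name=name, mask=mask.astype(bool),
                            n_missing=int(missing.sum()))


def stratum_filter(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    """Return the sub-cohort satisfying the named stratum predicate."""
    return cohort.loc[stratum_selection(cohort, name).mask]
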