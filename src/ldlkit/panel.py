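"""Lipid panel records and validation.

A lipid panel holds one patient's measured values in mg/dL: total cholesterol
(TC), HDL-C and triglycerides (TG) are required; a reference LDL-C
(ultracentrifugation-equivalent), VLDL-C and Lp(a) cholesterol are optional.
Non-HDL-C is always the derived quantity TC − HDL-C.

Validation mirrors standard clinical-laboratory exclusion rules: records with
a missing required analyte, a negative concentration, or TC < HDL-C (a
physical impossibility, since HDL cholesterol is a component of TC) are
rejected with a structured reason rather than silently dropped.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: canonical cohort columns produced by validation
REQUIRED_COLUMNS = ("tc", "hdl", "tg")
OPTIONAL_LIPIDS = ("ldl_ref", "vldl", "lpa_c")


@dataclass(frozen=True)
class LipidPanel:
    """One patient's lipid panel, all values in mg/dL."""

    tc: float
    hdl: float
    tg: float
    ldl_ref: float | None = None
    vldl: float | None = None
    lpa_c: float | None = None

    @property
    def non_hdl(self) -> float:
        """Non-HDL cholesterol, exactly TC − HDL-C."""
        return self.tc - self.hdl


@dataclass(frozen=True)
class Rejection:
    """A rejected record and the first rule it violated."""

    reason: str
    record: Mapping[str, Any] | None = None


def _missing(value: Any) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return True


def validate_panel(
    record: Mapping[str, Any], *, require_reference: bool = False
) -> LipidPanel | Rejection:
    """Validate one raw record; return a :class:`LipidPanel` or a :class:`Rejection`.

    Reasons, checked in order: ``missing_tc`` / ``missing_hdl`` / ``missing_tg``
    (NaN counts as missing), ``missing_ldl_ref`` when *require_reference*,
    ``negative_<field>``, and ``tc_lt_hdl``.
    """
    for field in REQUIRED_COLUMNS:
        if _missing(record.get(field)):
            return Rejection(f"missing_{field}", record)
    if require_reference and _missing(record.get("ldl_ref")):
        return Rejection("missing_ldl_ref", record)

    tc, hdl, tg = (float(record[f]) for f in REQUIRED_COLUMNS)
    for name, value in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if value < 0:
            return Rejection(f"negative_{name}", record)
    if tc < hdl:
        return Rejection("tc_lt_hdl", record)

    optional = {
        f: (None if _missing(record.get(f)) else float(record[f]))
        for f in OPTIONAL_LIPIDS
    }
    return LipidPanel(tc=tc, hdl=hdl, tg=tg, **optional)


def validate_cohort(
    frame: pd.DataFrame, *, require_reference: bool = False
) -> tuple[pd.DataFrame, Counter]:
    """Vectorised validation of a cohort table.

    Returns the accepted rows (with a derived ``non_hdl`` column) and a
    counter of rejection reasons. Each rejected row is counted once, under
    the first violated rule in the same order as :func:`validate_panel`.
    """
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise ValidationError(f"cohort table lacks required column {col!r}")

    reasons = pd.Series("", index=frame.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask.fillna(False) if mask.dtype == object else mask
        reasons[(reasons == "") & mask] = reason

    for col in REQUIRED_COLUMNS:
        flag(pd.to_numeric(frame[col], errors="coerce").isna(), f"missing_{col}")
    if require_reference:
        if "ldl_ref" not in frame.columns:
            flag(pd.Series(True, index=frame.index), "missing_ldl_ref")
        else:
            flag(pd.to_numeric(frame["ldl_ref"], errors="coerce").isna(),
                 "missing_ldl_ref")
    numeric = {
        col: pd.to_numeric(frame[col], errors="coerce") for col in REQUIRED_COLUMNS
    }
    for col in REQUIRED_COLUMNS:
        flag(numeric[col] < 0, f"negative_{col}")
    flag(numeric["tc"] < numeric["hdl"], "tc_lt_hdl")

    accepted = frame.loc[reasons == ""].copy()
    for col in REQUIRED_COLUMNS:
        accepted[col] = numeric[col].loc[accepted.index]
    accepted["non_hdl"] = accepted["tc"] - accepted["hdl"]
    rejected = Counter(reasons[reasons != ""])
    return accepted, rejected


def panels_to_frame(panels: list[LipidPanel]) -> pd.DataFrame:
    """Convert a list of panels to the canonical cohort DataFrame."""
    frame = pd.DataFrame(
        {
            "tc": [p.tc for p in panels],
            "hdl": [p.hdl for p in panels],
            "tg": [p.tg for p in panels],
            "ldl_ref": [np.nan if p.ldl_ref is None else p.ldl_ref for p in panels],
            "vldl": [np.nan if p.vldl is None else p.vldl for p in panels],
            "lpa_c": [np.nan if p.lpa_c is None else p.lpa_c for p in panels],
        }
    )
    frame["non_hdl"] = frame["tc"] - frame["hdl"]
    return frame
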