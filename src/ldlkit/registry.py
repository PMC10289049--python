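"""The LDL-C equation registry and estimation engine.

Twenty-three closed-form LDL-C estimators from the clinical literature, plus
the extended-TG Martin/Hopkins variant, are shipped as data-driven
definitions (``ldlkit/data/equations.tsv``). Each belongs to one of four
structural families:

``fixed_ratio``
    LDL = TC − HDL − TG/k, a fixed TG:VLDL-C divisor (Friedewald k = 5).
``linear``
    LDL = α·TC + β·HDL + γ·TG + δ.
``table_factor``
    Friedewald's structure with the divisor replaced by a lookup into a 2-D
    TG × non-HDL-C factor table (Martin/Hopkins).
``quadratic``
    Linear terms plus TG·non-HDL interaction and TG² curvature (Sampson).

The canonical internal unit is mg/dL. Equations published in mmol/L are
converted once at registry-build time (cholesterol ×38.67, TG ×88.57);
estimation never branches on units. Estimates are returned unrounded and
unclipped — a negative estimate is meaningful to downstream classification.
"""
from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

import numpy as np

from .exceptions import TGDomainError, UnknownEquationError, ValidationError
from .factor_table import load_factor_table, table_factor_ldl
from .panel import LipidPanel

FAMILIES = ("fixed_ratio", "linear", "table_factor", "quadratic")

#: unit conversion constants (mmol/L → mg/dL)
CHOL_MGDL_PER_MMOLL = 38.67
TG_MGDL_PER_MMOLL = 88.57


@dataclass(frozen=True)
class EquationDefinition:
    """One registry entry; coefficients are in mg/dL-equivalent form."""

    id: str
    family: str
    coefficients: Mapping[str, float]
    tg_domain: tuple[float, float]
    source_units: str
    citation: str
    role: str = "primary"
    table: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(
                f"equation {self.id!r}: family {self.family!r} not one of {FAMILIES}"
            )
        if self.family == "fixed_ratio" and self.coefficients["k"] <= 0:
            raise ValidationError(f"equation {self.id!r}: divisor must be positive")


def _convert_to_mgdl(family: str, coef: dict[str, float], units: str) -> dict:
    """Convert source-unit coefficients to mg/dL-equivalent form.

    For a concentration-linear form published in mmol/L, multiplying the
    whole equation by 38.67 leaves the TC/HDL coefficients unchanged and
    rescales the TG coefficient by 38.67/88.57, the intercept by 38.67, and
    (for fixed_ratio) the divisor by 88.57/38.67.
    """
    if units == "mg/dL":
        return coef
    if units != "mmol/L":
        raise ValidationError(f"unknown source units {units!r}")
    out = dict(coef)
    if "k" in out:
        out["k"] = out["k"] * TG_MGDL_PER_MMOLL / CHOL_MGDL_PER_MMOLL
    if "gamma" in out:
        out["gamma"] = out["gamma"] * CHOL_MGDL_PER_MMOLL / TG_MGDL_PER_MMOLL
    if "delta" in out:
        out["delta"] = out["delta"] * CHOL_MGDL_PER_MMOLL
    if "tg_nonhdl" in out:
        out["tg_nonhdl"] = out["tg_nonhdl"] / TG_MGDL_PER_MMOLL
    if "tg_sq" in out:
        out["tg_sq"] = out["tg_sq"] * CHOL_MGDL_PER_MMOLL / TG_MGDL_PER_MMOLL ** 2
    return out


_COEF_FIELDS = {
    "fixed_ratio": ("k",),
    "linear": ("alpha", "beta", "gamma", "delta"),
    "quadratic": ("alpha", "beta", "gamma", "tg_nonhdl", "tg_sq", "delta"),
    "table_factor": (),
}


class EquationRegistry:
    """Ordered mapping of equation id → :class:`EquationDefinition`."""

    def __init__(self, definitions: list[EquationDefinition]):
        self._by_id = {d.id: d for d in definitions}
        if len(self._by_id) != len(definitions):
            raise ValidationError("duplicate equation ids in registry")

    def __getitem__(self, eq_id: str) -> EquationDefinition:
        try:
            return self._by_id[eq_id]
        except KeyError:
            raise UnknownEquationError(eq_id, tuple(self._by_id)) from None

    def __iter__(self) -> Iterator[EquationDefinition]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, eq_id: str) -> bool:
        return eq_id in self._by_id

    def ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    def primary_ids(self) -> tuple[str, ...]:
        """The 23 primary equations (excludes the extended-TG variant)."""
        return tuple(d.id for d in self if d.role == "primary")


def _load_definitions() -> list[EquationDefinition]:
    text = (resources.files("ldlkit.data") / "equations.tsv").read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.DictReader(_io.StringIO("\n".join(lines)), delimiter="\t")
    defs = []
    for row in reader:
        family = row["family"]
        coef = {
            name: float(row[name])
            for name in _COEF_FIELDS[family]
            if row[name] != ""
        }
        for name in _COEF_FIELDS[family]:
            coef.setdefault(name, 0.0)
        defs.append(
            EquationDefinition(
                id=row["id"],
                role=row["role"],
                family=family,
                coefficients=_convert_to_mgdl(family, coef, row["source_units"]),
                tg_domain=(float(row["tg_lo"]), float(row["tg_hi"])),
                source_units=row["source_units"],
                citation=row["citation"],
                table=row["table"] or None,
            )
        )
    return defs


@lru_cache(maxsize=1)
def default_registry() -> EquationRegistry:
    """The packaged registry: 23 primary equations + extended-TG variant."""
    return EquationRegistry(_load_definitions())


# --- estimation engine -----------------------------------------------------

def fixed_ratio_ldl(tc, hdl, tg, k: float):
    """LDL = TC − HDL − TG/k."""
    return np.asarray(tc, float) - np.asarray(hdl, float) - np.asarray(tg, float) / k


def linear_ldl(tc, hdl, tg, coef: Mapping[str, float]):
    """LDL = α·TC + β·HDL + γ·TG + δ."""
    return (
        coef["alpha"] * np.asarray(tc, float)
        + coef["beta"] * np.asarray(hdl, float)
        + coef["gamma"] * np.asarray(tg, float)
        + coef["delta"]
    )


def quadratic_ldl(tc, hdl, tg, coef: Mapping[str, float]):
    """LDL = α·TC + β·HDL + γ·TG + d·TG·(TC−HDL) + e·TG² + δ."""
    tc = np.asarray(tc, float)
    hdl = np.asarray(hdl, float)
    tg = np.asarray(tg, float)
    return (
        coef["alpha"] * tc
        + coef["beta"] * hdl
        + coef["gamma"] * tg
        + coef["tg_nonhdl"] * tg * (tc - hdl)
        + coef["tg_sq"] * tg * tg
        + coef["delta"]
    )


def estimate_ldl(
    panel,
    equation: EquationDefinition | str,
    *,
    registry: EquationRegistry | None = None,
    override_tg_domain: bool = False,
):
    """Apply one equation to a panel (or arrays of panels); mg/dL.

    *panel* may be a :class:`~ldlkit.panel.LipidPanel`, a mapping with
    ``tc``/``hdl``/``tg`` keys (e.g. a DataFrame), or a (tc, hdl, tg) tuple
    of scalars/arrays. TG values outside the equation's validity domain
    raise :class:`TGDomainError` unless *override_tg_domain* is set.
    """
    if isinstance(equation, str):
        equation = (registry or default_registry())[equation]

    if isinstance(panel, LipidPanel):
        tc, hdl, tg = panel.tc, panel.hdl, panel.tg
    elif isinstance(panel, tuple):
        tc, hdl, tg = panel
    else:
        tc, hdl, tg = panel["tc"], panel["hdl"], panel["tg"]
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)

    if not override_tg_domain:
        lo, hi = equation.tg_domain
        bad = (tg < lo) | (tg >= hi)
        if np.any(bad):
            offender = float(np.atleast_1d(tg)[np.atleast_1d(bad)][0])
            raise TGDomainError(f"equation {equation.id!r}", offender, lo, hi,
                                hint="pass override_tg_domain=True to force")

    if equation.family == "fixed_ratio":
        out = fixed_ratio_ldl(tc, hdl, tg, equation.coefficients["k"])
    elif equation.family == "linear":
        out = linear_ldl(tc, hdl, tg, equation.coefficients)
    elif equation.family == "quadratic":
        out = quadratic_ldl(tc, hdl, tg, equation.coefficients)
    else:  # table_factor
        out = np.asarray(
            table_factor_ldl(tc, hdl, tg, load_factor_table(equation.table))
        )
    return float(out) if out.ndim == 0 else out
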