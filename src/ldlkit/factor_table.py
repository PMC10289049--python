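"""Adjustable TG:VLDL-C factor lookup tables (Martin/Hopkins).

The Friedewald equation estimates VLDL-C as TG/5; the Martin/Hopkins approach
replaces the fixed divisor with a patient-specific factor read from a 2-D
lookup table indexed by TG and non-HDL-C strata. The standard table covers
TG < 400 mg/dL (factors 3.1–9.5); the extended variant covers TG 400–799
mg/dL. Both ship as plain-text assets under ``ldlkit/data`` with recorded
content digests so an accidental edit is caught by the test suite.

All strata are half-open ``[low, high)``: a TG exactly on a boundary falls in
the upper stratum. Non-HDL-C values beyond the last stratum edge fall in the
last stratum.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .exceptions import TGDomainError, ValidationError

#: sha256 digests of the shipped assets, recorded at packaging time
ASSET_DIGESTS = {
    "standard": "52fa59f5f65ace6e0915ab54ab63d93b63427fd73c0a11bc202a05b5e9e8250d",
    "extended": "077ba2661819e5abef96b0f9bcb9900ba359b2ce18f6b66d93684582f8ebbb88",
}


@dataclass(frozen=True)
class FactorTable:
    """2-D lookup of positive TG:VLDL-C divisors.

    ``tg_edges`` has ``m+1`` entries delimiting m half-open TG strata;
    ``nonhdl_edges`` has ``n+1`` entries (last is +inf); ``factors`` is m×n.
    """

    variant: str
    tg_edges: np.ndarray
    nonhdl_edges: np.ndarray
    factors: np.ndarray

    def __post_init__(self):
        tg, nh, f = self.tg_edges, self.nonhdl_edges, self.factors
        if f.shape != (len(tg) - 1, len(nh) - 1):
            raise ValidationError("factor matrix shape does not match strata edges")
        if np.any(np.diff(tg) <= 0) or np.any(np.diff(nh) <= 0):
            raise ValidationError("strata edges must be strictly increasing")
        if np.any(f <= 0):
            raise ValidationError("all factors must be strictly positive")

    @property
    def tg_range(self) -> tuple[float, float]:
        return float(self.tg_edges[0]), float(self.tg_edges[-1])

    def lookup(self, tg, non_hdl):
        """Return the factor for (tg, non_hdl); piecewise-constant in both.

        Raises :class:`TGDomainError` when tg falls outside the table's TG
        range, directing the caller to the other variant.
        """
        tg = np.asarray(tg, dtype=float)
        non_hdl = np.asarray(non_hdl, dtype=float)
        lo, hi = self.tg_range
        bad = (tg < lo) | (tg >= hi)
        if np.any(bad):
            offender = float(np.atleast_1d(tg)[np.atleast_1d(bad)][0])
            other = "extended" if self.variant == "standard" else "standard"
            raise TGDomainError(
                f"the {self.variant} factor table", offender, lo, hi,
                hint=f"use the {other} variant for this TG level",
            )
        i = np.searchsorted(self.tg_edges, tg, side="right") - 1
        j = np.searchsorted(self.nonhdl_edges, non_hdl, side="right") - 1
        j = np.clip(j, 0, self.factors.shape[1] - 1)  # last stratum absorbs
        out = self.factors[i, j]
        return float(out) if out.ndim == 0 else out


def _parse_table(text: str, variant: str) -> FactorTable:
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    header, body = rows[0], rows[1:]
    tg_edges = [float(r[0]) for r in body] + [float(body[-1][1])]
    # non-HDL edges are encoded in the column names: lt_100, 100_129, ..., ge_220
    nonhdl_edges = [0.0]
    for name in header[2:]:
        parts = name.replace("nonhdl_", "").split("_")
        if parts[0] == "lt":
            nonhdl_edges[0] = 0.0
            nonhdl_edges.append(float(parts[1]))
        elif parts[0] != "ge":
            nonhdl_edges.append(float(parts[1]) + 1.0)
    nonhdl_edges.append(np.inf)
    factors = np.array([[float(x) for x in r[2:]] for r in body])
    return FactorTable(
        variant=variant,
        tg_edges=np.asarray(tg_edges, dtype=float),
        nonhdl_edges=np.asarray(nonhdl_edges, dtype=float),
        factors=factors,
    )


def asset_text(variant: str) -> str:
    res = resources.files("ldlkit.data") / f"martin_hopkins_{variant}.tsv"
    return res.read_text()


def asset_digest(variant: str) -> str:
    return hashlib.sha256(asset_text(variant).encode()).hexdigest()


@lru_cache(maxsize=None)
def load_factor_table(variant: str = "standard") -> FactorTable:
    """Load a packaged factor table (``standard`` or ``extended``)."""
    if variant not in ASSET_DIGESTS:
        raise ValidationError(
            f"unknown factor-table variant {variant!r}; "
            f"available: {', '.join(ASSET_DIGESTS)}"
        )
    return _parse_table(asset_text(variant), variant)


def lookup_factor(tg, non_hdl, table: FactorTable):
    """Functional form of :meth:`FactorTable.lookup`."""
    return table.lookup(tg, non_hdl)


def table_factor_ldl(tc, hdl, tg, table: FactorTable):
    """LDL-C = TC − HDL − TG / factor(TG, non-HDL-C), mg/dL."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    out = tc - hdl - tg / table.lookup(tg, tc - hdl)
    return float(out) if out.ndim == 0 else out


def adjustable_factor_ldl(tc, hdl, tg):
    """Composite Martin/Hopkins estimate: standard table below TG 400 mg/dL,
    extended table for 400–799. Raises for TG ≥ 800."""
    tc, hdl, tg = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (tc, hdl, tg))
    )
    scalar = tg.ndim == 0
    tc, hdl, tg = np.atleast_1d(tc, hdl, tg)
    if np.any(tg >= 800):
        offender = float(tg[tg >= 800][0])
        raise TGDomainError("the composite adjustable-factor estimator",
                            offender, 0, 800)
    out = np.empty_like(tg)
    lo = tg < 400
    if np.any(lo):
        out[lo] = table_factor_ldl(tc[lo], hdl[lo], tg[lo],
                                   load_factor_table("standard"))
    if np.any(~lo):
        out[~lo] = table_factor_ldl(tc[~lo], hdl[~lo], tg[~lo],
                                    load_factor_table("extended"))
    return float(out[0]) if scalar else out
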