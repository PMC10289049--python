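"""Independent transcriptions of every LDL-C equation, used as test oracles.

Each function below is a standalone, scalar, hand-coded transcription of one
equation, written directly from its published/registered form with literal
numbers — deliberately sharing no code or data files with the package's
estimation engine. The Martin/Hopkins oracle re-reads the factor-table
assets with the stdlib csv module and a linear scan, independent of the
package's vectorised lookup.
"""
from __future__ import annotations

import csv
import pathlib

_CHOL = 38.67  # mg/dL per mmol/L, cholesterol
_TG = 88.57    # mg/dL per mmol/L, triglycerides


def friedewald(tc, hdl, tg):
    return tc - hdl - tg / 5


def delong(tc, hdl, tg):
    return tc - hdl - 0.16 * tg


def puavilai(tc, hdl, tg):
    return tc - hdl - tg / 6


def vujovic(tc, hdl, tg):
    return tc - hdl - tg / 6.85


def ephraim(tc, hdl, tg):
    return tc - hdl - tg / 8.5


def ghasemi(tc, hdl, tg):
    return tc - hdl - tg / 4


def bauer(tc, hdl, tg):
    return tc - hdl - tg / 7.5


def rao(tc, hdl, tg):
    return 0.98 * tc - 0.87 * hdl - 0.19 * tg


def hattori(tc, hdl, tg):
    return 0.94 * tc - 0.94 * hdl - 0.19 * tg


def anandaraja(tc, hdl, tg):
    return 0.9 * tc - 0.18 * tg - 28


def teerakanchana(tc, hdl, tg):
    return 0.903 * tc - 0.729 * hdl - 0.117 * tg - 4.22


def ahmadi(tc, hdl, tg):
    return tc / 1.19 + tg / 1.9 - hdl / 1.1 - 38


def chen(tc, hdl, tg):
    return 0.9 * tc - 0.9 * hdl - 0.1 * tg


def cordova(tc, hdl, tg):
    return 0.75 * (tc - hdl)


def dansethakul(tc, hdl, tg):
    # published in mmol/L; convert in, evaluate, convert out
    ldl_mmol = (0.90 * tc / _CHOL - 0.88 * hdl / _CHOL
                - 0.23 * tg / _TG + 0.05)
    return ldl_mmol * _CHOL


def rasouli(tc, hdl, tg):
    return 0.83 * tc - 0.83 * hdl - 0.071 * tg


def lee_hu(tc, hdl, tg):
    return 0.727 * tc - 0.201 * tg


def choi(tc, hdl, tg):
    return 1.04 * tc - 1.04 * hdl - 0.175 * tg


def molavi(tc, hdl, tg):
    return 0.94 * tc - 0.94 * hdl - 0.18 * tg


def orejon(tc, hdl, tg):
    return 0.94 * tc - 0.94 * hdl - 0.14 * tg + 2.0


def sampson(tc, hdl, tg):
    return (tc / 0.948 - hdl / 0.971
            - (tg / 8.56 + tg * (tc - hdl) / 2140 - tg * tg / 16100)
            - 9.44)


def saiedullah(tc, hdl, tg):
    return tc - hdl - 0.2 * tg - 5e-05 * tg * tg - 3.0


def _read_factor_rows(variant):
    data_dir = (pathlib.Path(__file__).resolve().parents[1]
                / "src" / "ldlkit" / "data")
    rows = []
    with open(data_dir / f"martin_hopkins_{variant}.tsv") as fh:
        body = [ln for ln in fh if not ln.startswith("#")]
    for rec in list(csv.reader(body, delimiter="\t"))[1:]:
        rows.append((float(rec[0]), float(rec[1]), [float(x) for x in rec[2:]]))
    return rows


_NONHDL_LOWS = [0.0, 100.0, 130.0, 160.0, 190.0, 220.0]


def martin_hopkins_factor(tg, non_hdl, variant="standard"):
    """Two-step linear-scan factor lookup (half-open strata)."""
    col = 0
    for j, low in enumerate(_NONHDL_LOWS):
        if non_hdl >= low:
            col = j
    for lo, hi, factors in _read_factor_rows(variant):
        if lo <= tg < hi:
            return factors[col]
    raise ValueError(f"TG {tg} outside {variant} table")


def martin_hopkins(tc, hdl, tg):
    return tc - hdl - tg / martin_hopkins_factor(tg, tc - hdl, "standard")


def martin_hopkins_extended(tc, hdl, tg):
    return tc - hdl - tg / martin_hopkins_factor(tg, tc - hdl, "extended")


ORACLES = {
    "friedewald": friedewald,
    "delong": delong,
    "puavilai": puavilai,
    "vujovic": vujovic,
    "ephraim": ephraim,
    "ghasemi": ghasemi,
    "bauer": bauer,
    "rao": rao,
    "hattori": hattori,
    "anandaraja": anandaraja,
    "teerakanchana": teerakanchana,
    "ahmadi": ahmadi,
    "chen": chen,
    "cordova": cordova,
    "dansethakul": dansethakul,
    "rasouli": rasouli,
    "lee_hu": lee_hu,
    "choi": choi,
    "molavi": molavi,
    "orejon": orejon,
    "sampson": sampson,
    "saiedullah": saiedullah,
    "martin_hopkins": martin_hopkins,
    "martin_hopkins_extended": martin_hopkins_extended,
}
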