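"""Synthetic lipid-panel cohort generator.

Real clinical-laboratory lipid data are proprietary; this module generates
cohorts with the statistical structure the evaluation pipeline assumes:

* right-skewed marginals for reference LDL-C, HDL-C, TG and Lp(a)-C, each a
  log-normal law parameterized by a (median, q25, q75) triple so the sample
  median is calibrated by construction (defaults: LDL 114 (90–141), HDL 51
  (42–63), TG 114 (81–164), Lp(a)-C 6 (4–10) mg/dL);
* a heterogeneous TG:VLDL-C ratio r, log-normal with median 5.0 (4.4–5.9),
  whose log-location rises with log-TG (``ratio_tg_coupling``) and falls
  with the log of the non-VLDL cholesterol burden (LDL + Lp(a);
  ``ratio_nonhdl_coupling``) — the two gradients the published
  adjustable-factor table encodes — truncated to physiologic bounds;
  VLDL-C = TG/r;
* an exact cholesterol accounting identity
  TC = LDL-C + HDL-C + VLDL-C + Lp(a)-C, so TC is emergent (median ≈ 193);
* covariates at fixed proportions (53.7% women; fasting 19.4% /
  non-fasting 11.9% / unknown 68.7%; age bands 1.2/58.3/39.8/0.7%) and
  clinical labs calibrated so flag prevalences match the population the
  defaults describe. Flags are drawn independently of lipids (a documented
  v1 simplification).

A single ``numpy.random.default_rng`` stream seeded from the config drives
everything; identical config + seed reproduces the cohort byte-for-byte.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_Z75 = float(stats.norm.ppf(0.75))


class QuantileTriple(BaseModel):
    """Median and quartiles (q25 < median < q75, all positive)."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    q25: float = Field(gt=0)
    q75: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.q25 < self.median < self.q75):
            raise ValueError("need q25 < median < q75")
        return self


def lognormal_params_from_quantiles(
    median: float, q25: float, q75: float
) -> tuple[float, float]:
    """(location, scale) of the log-normal law with the given median/IQR.

    location = ln(median); scale = ln(q75/q25) / (2·z₀.₇₅). The implied law
    reproduces the requested median exactly, and the requested IQR exactly
    when the quantiles are geometrically symmetric (q75/median =
    median/q25); otherwise the two one-sided scales are averaged and the
    discrepancy is logged.
    """
    if not (0 < q25 < median < q75):
        raise ValidationError("need 0 < q25 < median < q75")
    location = math.log(median)
    scale = math.log(q75 / q25) / (2.0 * _Z75)
    up, down = q75 / median, median / q25
    if not math.isclose(up, down, rel_tol=1e-6):
        implied = (median / math.exp(scale * _Z75),
                   median * math.exp(scale * _Z75))
        logger.debug(
            "asymmetric quantiles (median=%g, q25=%g, q75=%g): implied IQR "
            "(%.4g, %.4g) differs from the requested one",
            median, q25, q75, *implied,
        )
    return location, scale


class GeneratorConfig(BaseModel):
    """Cohort size, seed, marginal calibrations and covariate proportions."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=100_000, ge=1)
    seed: int = 0

    ldl: QuantileTriple = QuantileTriple(median=114, q25=90, q75=141)
    hdl: QuantileTriple = QuantileTriple(median=51, q25=42, q75=63)
    tg: QuantileTriple = QuantileTriple(median=114, q25=81, q75=164)
    lpa_c: QuantileTriple = QuantileTriple(median=6, q25=4, q75=10)
    ratio: QuantileTriple = QuantileTriple(median=5.0, q25=4.4, q75=5.9)

    #: d ln(ratio location) / d ln(TG); > 0 makes the TG:VLDL-C ratio rise
    #: with TG, the direction encoded by the adjustable-factor table
    ratio_tg_coupling: float = 0.3
    #: d ln(ratio location) / d ln(LDL + Lp(a)-C); < 0 makes the ratio fall
    #: with the non-VLDL cholesterol burden, the adjustable-factor table's
    #: non-HDL-C gradient (centred on the sample median, so the marginal
    #: ratio median stays calibrated)
    ratio_nonhdl_coupling: float = -0.25
    ratio_bounds: tuple[float, float] = (3.0, 13.0)

    p_female: float = Field(default=0.537, ge=0, le=1)
    fasting_props: dict[str, float] = {
        "fasting": 0.194, "non_fasting": 0.119, "unknown": 0.687,
    }
    age_props: dict[str, float] = {
        "lt_18": 0.012, "18_59": 0.583, "ge_60": 0.398, "unknown": 0.007,
    }

    p_ascvd: float = 0.0065
    p_hypertension: float = 0.0555
    p_diabetes_dx: float = 0.027
    #: probability each optional lab (eGFR, hsCRP, TSH, A1c, glucose) is present
    p_lab_available: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _proportions(self):
        for name, props in (("fasting_props", self.fasting_props),
                            ("age_props", self.age_props)):
            if any(not 0 <= p <= 1 for p in props.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.ratio_bounds[0] <= 0 or self.ratio_bounds[0] >= self.ratio_bounds[1]:
            raise ValueError("ratio_bounds must be positive and increasing")
        return self


def _draw_lognormal(rng, triple: QuantileTriple, n: int) -> np.ndarray:
    loc, scale = lognormal_params_from_quantiles(
        triple.median, triple.q25, triple.q75
    )
    return rng.lognormal(mean=loc, sigma=scale, size=n)


def _draw_categorical(rng, props: dict[str, float], n: int) -> np.ndarray:
    names = list(props)
    return rng.choice(names, size=n, p=[props[k] for k in names])


# lab models: parameters chosen so flag prevalences among records with the
# lab present match the population the defaults describe (kidney disease
# 7.3%, inflammation 8.5%, TSH <0.5 0.8%, TSH >4.5 0.55%, A1c/glucose
# criteria ~1% each on top of the diagnosis flag)
_EGFR_MU, _EGFR_SIGMA = 90.0, 20.64
_HSCRP_MED, _HSCRP_SIGMA = 1.0, 0.504
_TSH_MED, _TSH_SIGMA = 1.457, 0.444
_A1C_MED, _A1C_SIGMA = 5.5, 0.07
_GLUCOSE_MED, _GLUCOSE_SIGMA = 95.0, 0.12


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate a synthetic cohort as a DataFrame of lipid panels + covariates.

    Keyword overrides are applied on top of *config* (e.g.
    ``generate_cohort(n=1000, seed=7)``). Columns: tc, hdl, tg, non_hdl,
    ldl_ref, vldl, lpa_c, age, sex, fasting, ascvd, hypertension,
    diabetes_dx, egfr, a1c, fasting_glucose, hscrp, tsh.

    Per record the lipid block satisfies, exactly by construction::

        tc = ldl_ref + hdl + vldl + lpa_c      vldl * ratio = tg
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n

    ldl = _draw_lognormal(rng, config.ldl, n)
    hdl = _draw_lognormal(rng, config.hdl, n)
    tg = _draw_lognormal(rng, config.tg, n)
    lpa = _draw_lognormal(rng, config.lpa_c, n)

    loc_r, scale_r = lognormal_params_from_quantiles(
        config.ratio.median, config.ratio.q25, config.ratio.q75
    )
    log_base = np.log(ldl + lpa)  # cholesterol burden the VLDL estimate competes with
    shift = (
        config.ratio_tg_coupling * (np.log(tg) - math.log(config.tg.median))
        + config.ratio_nonhdl_coupling * (log_base - np.median(log_base))
    )
    ratio = np.exp(loc_r + shift + scale_r * rng.standard_normal(n))
    ratio = np.clip(ratio, *config.ratio_bounds)

    vldl = tg / ratio
    tc = ldl + hdl + vldl + lpa

    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    fasting = _draw_categorical(rng, config.fasting_props, n)
    age_band = _draw_categorical(rng, config.age_props, n)
    age = np.full(n, np.nan)
    for band, lo, hi in (("lt_18", 2.0, 18.0), ("18_59", 18.0, 60.0),
                         ("ge_60", 60.0, 90.0)):
        m = age_band == band
        age[m] = rng.uniform(lo, hi, size=int(m.sum()))

    ascvd = rng.random(n) < config.p_ascvd
    hypertension = rng.random(n) < config.p_hypertension
    diabetes_dx = rng.random(n) < config.p_diabetes_dx

    def lab(values: np.ndarray) -> np.ndarray:
        present = rng.random(n) < config.p_lab_available
        return np.where(present, values, np.nan)

    egfr = lab(np.maximum(rng.normal(_EGFR_MU, _EGFR_SIGMA, n), 1.0))
    hscrp = lab(rng.lognormal(math.log(_HSCRP_MED), _HSCRP_SIGMA, n))
    tsh = lab(rng.lognormal(math.log(_TSH_MED), _TSH_SIGMA, n))
    a1c = lab(rng.lognormal(math.log(_A1C_MED), _A1C_SIGMA, n))
    glucose = lab(rng.lognormal(math.log(_GLUCOSE_MED), _GLUCOSE_SIGMA, n))

    return pd.DataFrame(
        {
            "tc": tc,
            "hdl": hdl,
            "tg": tg,
            "non_hdl": tc - hdl,
            "ldl_ref": ldl,
            "vldl": vldl,
            "lpa_c": lpa,
            "age": age,
            "sex": sex,
            "fasting": fasting,
            "ascvd": ascvd,
            "hypertension": hypertension,
            "diabetes_dx": diabetes_dx,
            "egfr": egfr,
            "a1c": a1c,
            "fasting_glucose": glucose,
            "hscrp": hscrp,
            "tsh": tsh,
        }
    )
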