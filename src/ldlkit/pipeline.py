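"""End-to-end accuracy evaluation of LDL-C equations on a cohort.

For each requested equation × stratum the pipeline computes guideline-
category concordance (overall and per category), signed and relative error
summaries, and — for the configured alternative equations — confirmed upward
reclassification versus Friedewald at the treatment cutpoint. Outputs are
three delimited reports (a concordance matrix of equations × the 8
categories, an error-summary listing, and a reclassification listing), an
accounting table of denominators, and a machine-readable ``summary.json``
carrying full-precision values and provenance (package version, config hash,
seed). Human-readable percentages and mg/dL values are rounded to 0.1 at the
presentation layer only.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classification import CategoryScheme, concordance, default_scheme
from .error_metrics import summarize_errors
from .exceptions import ValidationError
from .io import read_cohort
from .reclassification import upward_reclassification
from .registry import EquationRegistry, default_registry
from .strata import AVAILABLE_STRATA, stratum_selection
from .synth import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_STRATA = (
    "all", "tg_lt_400", "tg_150_399", "age_lt_18", "age_18_59", "age_ge_60",
    "female", "male", "fasting", "non_fasting", "fasting_unknown",
    "ascvd", "hypertension", "kidney_disease", "diabetes", "inflammation",
    "thyroid_dysfunction",
)
DEFAULT_ALTERNATIVES = ("martin_hopkins", "sampson", "chen", "puavilai", "delong")


class RunConfig(BaseModel):
    """Configuration for one evaluation run."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    input: Path | None = None
    simulate: GeneratorConfig | None = None
    equations: tuple[str, ...] | None = None  # None → all 23 primary
    strata: tuple[str, ...] = DEFAULT_STRATA
    orientation: str = "reference"
    tolerance: float = Field(default=5.0, gt=0)
    cutpoint: float = 70.0
    reclassify_alternatives: tuple[str, ...] = DEFAULT_ALTERNATIVES
    reclassify_tg_ranges: tuple[tuple[float, float], ...] = ((0.0, 400.0),
                                                            (150.0, 400.0))
    outdir: Path | None = None
    seed: int | None = None


@dataclass
class EvaluationReport:
    """In-memory result of :func:`run_evaluation`."""

    concordance: pd.DataFrame
    errors: pd.DataFrame
    reclassification: pd.DataFrame
    accounting: pd.DataFrame
    summary: dict
    written: list[Path] = field(default_factory=list)


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only, not the output location
    payload = config.model_dump_json(exclude={"outdir"})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _obtain_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    if (config.input is None) == (config.simulate is None):
        raise ValidationError("exactly one of input/simulate must be configured")
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = sim.model_copy(update={"seed": config.seed})
        logger.info("simulating cohort: n=%d seed=%d", sim.n, sim.seed)
        return generate_cohort(sim), {}
    result = read_cohort(config.input, require_reference=True)
    return result.frame, dict(result.rejections)


def _masked_estimates(cohort: pd.DataFrame, equation, registry) -> np.ndarray:
    """Equation estimates with NaN outside the equation's TG domain."""
    if isinstance(equation, str):
        equation = registry[equation]
    tg = cohort["tg"].to_numpy(dtype=float)
    lo, hi = equation.tg_domain
    mask = (tg >= lo) & (tg < hi)
    out = np.full(len(cohort), np.nan)
    if mask.any():
        from .registry import estimate_ldl

        out[mask] = estimate_ldl(cohort.loc[mask], equation)
    return out


def run_evaluation(
    config: RunConfig,
    *,
    cohort: pd.DataFrame | None = None,
    registry: EquationRegistry | None = None,
    scheme: CategoryScheme | None = None,
) -> EvaluationReport:
    """Run the full evaluation; write reports when ``config.outdir`` is set.

    The cohort must carry a reference LDL-C (``ldl_ref``) for every record
    used; records lacking it are excluded and accounted for.
    """
    registry = registry or default_registry()
    scheme = scheme or default_scheme()
    rejections: dict = {}
    if cohort is None:
        cohort, rejections = _obtain_cohort(config)
    if "ldl_ref" not in cohort.columns:
        raise ValidationError(
            "evaluation requires a reference LDL-C column 'ldl_ref'"
        )
    eq_ids = config.equations or registry.primary_ids()
    for name in config.strata:
        if name not in AVAILABLE_STRATA:
            from .exceptions import UnknownStratumError

            raise UnknownStratumError(name, AVAILABLE_STRATA)

    n_total = len(cohort)
    ref = cohort["ldl_ref"].to_numpy(dtype=float)
    ref_ok = np.isfinite(ref)
    estimates = {eq: _masked_estimates(cohort, eq, registry) for eq in eq_ids}

    conc_rows, err_rows, acct_rows = [], [], []
    summary_eval: dict = {}
    for name in config.strata:
        sel = stratum_selection(cohort, name)
        mask = sel.mask.to_numpy()
        logger.info("stratum %s: n=%d (missing covariate: %d)",
                    name, int(mask.sum()), sel.n_missing)
        summary_eval[name] = {}
        for eq in eq_ids:
            est = estimates[eq]
            valid = mask & ref_ok & np.isfinite(est)
            n_valid = int(valid.sum())
            acct_rows.append({
                "stratum": name,
                "equation": eq,
                "n_cohort": n_total,
                "n_stratum": int(mask.sum()),
                "n_missing_covariate": sel.n_missing,
                "n_outside_stratum": n_total - int(mask.sum()) - sel.n_missing,
                "n_excluded_tg_domain_or_no_reference":
                    int(mask.sum()) - n_valid,
                "n_evaluated": n_valid,
            })
            if n_valid == 0:
                continue
            e, r = est[valid], ref[valid]
            conc = concordance(e, r, scheme, by=config.orientation)
            relative = bool(np.all(r > 0))
            errs = summarize_errors(e, r, tolerance=config.tolerance,
                                    relative=relative)
            conc_row = {
                "stratum": name, "equation": eq,
                "orientation": conc.orientation, "n": conc.n,
                "overall_pct": 100 * conc.overall,
            }
            for lab, p in zip(conc.labels, conc.per_category):
                conc_row[f"cat_{lab}_pct"] = 100 * p if np.isfinite(p) else np.nan
            conc_rows.append(conc_row)
            err_rows.append({
                "stratum": name, "equation": eq, "n": errs.n,
                "median_error": errs.median_error,
                "q25_error": errs.iqr_error[0],
                "q75_error": errs.iqr_error[1],
                "median_relative_error_pct": errs.median_relative_error,
                "q25_relative_error_pct":
                    errs.iqr_relative_error[0] if errs.iqr_relative_error else None,
                "q75_relative_error_pct":
                    errs.iqr_relative_error[1] if errs.iqr_relative_error else None,
                "frac_within_pct": 100 * errs.frac_within,
                "tolerance": errs.tolerance,
            })
            summary_eval[name][eq] = {
                "n": conc.n,
                "concordance_overall": conc.overall,
                "concordance_per_category": [
                    None if not np.isfinite(p) else p for p in conc.per_category
                ],
                "category_denominators": conc.denominators.tolist(),
                "median_error": errs.median_error,
                "iqr_error": list(errs.iqr_error),
                "median_relative_error": errs.median_relative_error,
                "frac_within": errs.frac_within,
            }

    recl_rows = []
    summary_recl: dict = {}
    can_reclassify = bool(ref_ok.all()) and n_total > 0
    if can_reclassify and config.reclassify_alternatives:
        for alt in config.reclassify_alternatives:
            summary_recl[alt] = {}
            for tg_range in config.reclassify_tg_ranges:
                res = upward_reclassification(
                    cohort, alt, tg_range=tuple(tg_range),
                    cutpoint=config.cutpoint, registry=registry,
                )
                recl_rows.append({
                    "equation": alt,
                    "tg_lo": tg_range[0], "tg_hi": tg_range[1],
                    "cutpoint": config.cutpoint,
                    "denominator": res.denominator,
                    "correct": res.correct,
                    "incorrect": res.incorrect,
                    "proportion_pct":
                        100 * res.proportion if res.defined else np.nan,
                })
                summary_recl[alt][f"tg_{tg_range[0]:g}_{tg_range[1]:g}"] = {
                    "denominator": res.denominator,
                    "correct": res.correct,
                    "incorrect": res.incorrect,
                    "proportion": res.proportion if res.defined else None,
                }

    concordance_frame = pd.DataFrame(conc_rows)
    errors_frame = pd.DataFrame(err_rows)
    recl_frame = pd.DataFrame(recl_rows)
    accounting_frame = pd.DataFrame(acct_rows)

    summary = {
        "provenance": {
            "package": "ldlkit",
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": (config.simulate.seed if config.simulate is not None
                     else config.seed),
            "orientation": config.orientation,
            "n_cohort": n_total,
            "rejections": rejections,
        },
        "evaluation": summary_eval,
        "reclassification": summary_recl,
    }

    report = EvaluationReport(
        concordance=concordance_frame,
        errors=errors_frame,
        reclassification=recl_frame,
        accounting=accounting_frame,
        summary=summary,
    )
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _round_numeric(frame: pd.DataFrame, exclude: Sequence[str] = ()) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col in exclude:
            continue
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(1)
    return out


def _write_report(report: EvaluationReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    targets = [
        ("category_concordance.csv", _round_numeric(report.concordance)),
        ("error_summary.csv", _round_numeric(report.errors, exclude=("tolerance",))),
        ("reclassification.csv", _round_numeric(report.reclassification,
                                                exclude=("tg_lo", "tg_hi",
                                                         "cutpoint"))),
        ("accounting.csv", report.accounting),
    ]
    for name, frame in targets:
        path = outdir / name
        frame.to_csv(path, index=False)
        report.written.append(path)
    path = outdir / "summary.json"
    with open(path, "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=False)
    report.written.append(path)
    logger.info("wrote %d report files to %s", len(report.written), outdir)
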