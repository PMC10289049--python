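"""Patient-level error summaries between estimated and reference LDL-C.

Sign convention: error = estimate − reference, so underestimation is
negative. Relative error is 100 × error / reference (%), requiring strictly
positive references. Quantiles use linear interpolation between order
statistics (numpy's default); the rule is recorded on the summary because
5-point test fixtures are sensitive to it even though large-cohort medians
are not.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

QUANTILE_RULE = "linear"  # interpolation between order statistics


@dataclass(frozen=True)
class ErrorSummary:
    """Median (IQR) signed and relative error plus a within-tolerance rate."""

    n: int
    median_error: float
    iqr_error: tuple[float, float]
    median_relative_error: float | None
    iqr_relative_error: tuple[float, float] | None
    frac_within: float
    tolerance: float
    quantile_rule: str = QUANTILE_RULE


def summarize_errors(
    estimates,
    references,
    *,
    tolerance: float = 5.0,
    relative: bool = True,
) -> ErrorSummary:
    """Summarize estimate − reference errors for paired LDL-C values.

    ``frac_within`` is the proportion with |error| strictly below
    *tolerance* (mg/dL). Set ``relative=False`` to skip the relative-error
    scale (required when references are not strictly positive).
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValidationError("estimates and references must have equal length")
    if est.size == 0:
        raise ValidationError("summarize_errors requires non-empty input")

    err = est - ref
    q25, med, q75 = np.quantile(err, [0.25, 0.5, 0.75], method=QUANTILE_RULE)

    med_rel = iqr_rel = None
    if relative:
        if np.any(ref <= 0):
            raise ValidationError(
                "relative errors require strictly positive references; "
                "pass relative=False to skip them"
            )
        rel = 100.0 * err / ref
        r25, rmed, r75 = np.quantile(rel, [0.25, 0.5, 0.75], method=QUANTILE_RULE)
        med_rel, iqr_rel = float(rmed), (float(r25), float(r75))

    return ErrorSummary(
        n=int(err.size),
        median_error=float(med),
        iqr_error=(float(q25), float(q75)),
        median_relative_error=med_rel,
        iqr_relative_error=iqr_rel,
        frac_within=float(np.mean(np.abs(err) < tolerance)),
        tolerance=float(tolerance),
    )
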