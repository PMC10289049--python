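"""Confirmed upward reclassification across a treatment cutpoint.

When a laboratory switches from Friedewald to an alternative equation, a
patient with Friedewald LDL-C below the cutpoint (default 70 mg/dL) may be
reclassified upward; the reclassification is *correct* when the reference
(ultracentrifugation) LDL-C is also at or above the cutpoint.

Boundary convention: "reclassified above the cutpoint" is implemented as
``>= cutpoint`` for both the alternative estimate and the reference, so the
below/at-or-above dichotomy partitions all values. Incorrect upward
reclassifications (alternative above, reference below) are counted and
reported separately.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .registry import EquationDefinition, EquationRegistry, default_registry, estimate_ldl


@dataclass(frozen=True)
class ReclassificationResult:
    """Counts and proportions for one alternative equation and TG range."""

    equation: str
    tg_range: tuple[float, float]
    cutpoint: float
    denominator: int          # Friedewald < cutpoint within TG range
    correct: int              # alternative >= cutpoint and reference >= cutpoint
    incorrect: int            # alternative >= cutpoint but reference < cutpoint
    n_reference_high: int     # denominator records whose reference >= cutpoint

    @property
    def proportion(self) -> float:
        """correct / denominator; NaN when the denominator is empty."""
        return self.correct / self.denominator if self.denominator else float("nan")

    @property
    def proportion_among_reference_high(self) -> float:
        """Secondary ratio: correct / (denominator with reference >= cutpoint)."""
        return (
            self.correct / self.n_reference_high
            if self.n_reference_high
            else float("nan")
        )

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def upward_reclassification(
    cohort: pd.DataFrame,
    alternative: EquationDefinition | str,
    *,
    tg_range: tuple[float, float] = (0.0, 400.0),
    cutpoint: float = 70.0,
    registry: EquationRegistry | None = None,
    baseline: EquationDefinition | str = "friedewald",
) -> ReclassificationResult:
    """Confirmed upward reclassification of *alternative* versus Friedewald.

    *cohort* must carry ``tc``/``hdl``/``tg``/``ldl_ref`` columns. The
    denominator is every record with TG in the half-open *tg_range* whose
    baseline (Friedewald) estimate is below *cutpoint*; the numerator is the
    subset whose alternative estimate and reference LDL-C are both at or
    above it. An empty denominator yields a flagged (NaN-proportion) result,
    never an exception.
    """
    registry = registry or default_registry()
    if isinstance(alternative, str):
        alternative = registry[alternative]
    if isinstance(baseline, str):
        baseline = registry[baseline]
    if "ldl_ref" not in cohort.columns or cohort["ldl_ref"].isna().any():
        raise ValidationError(
            "upward_reclassification requires a reference LDL-C (ldl_ref) "
            "for every record"
        )

    tg = cohort["tg"].to_numpy(dtype=float)
    in_range = (tg >= tg_range[0]) & (tg < tg_range[1])
    sub = cohort.loc[in_range]
    if len(sub) == 0:
        return ReclassificationResult(
            alternative.id, tg_range, cutpoint, 0, 0, 0, 0
        )

    base = np.asarray(estimate_ldl(sub, baseline, override_tg_domain=True))
    alt = np.asarray(estimate_ldl(sub, alternative, override_tg_domain=True))
    ref = sub["ldl_ref"].to_numpy(dtype=float)

    denom_mask = base < cutpoint
    up = denom_mask & (alt >= cutpoint)
    correct = up & (ref >= cutpoint)
    return ReclassificationResult(
        equation=alternative.id,
        tg_range=tg_range,
        cutpoint=cutpoint,
        denominator=int(denom_mask.sum()),
        correct=int(correct.sum()),
        incorrect=int((up & ~(ref >= cutpoint)).sum()),
        n_reference_high=int((denom_mask & (ref >= cutpoint)).sum()),
    )
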