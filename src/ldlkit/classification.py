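"""Guideline LDL-C categories and estimated-vs-reference concordance.

The eight treatment-guideline bins (<40, 40–54, 55–69, 70–99, 100–129,
130–159, 160–189, ≥190 mg/dL) are half-open ``[low, high)``: an LDL-C of
exactly 70 falls in "70–99". The lowest bin absorbs negative estimates.

Concordance is the proportion of paired estimated/reference LDL-C values
falling in the same category. Per-category concordance can be stratified
either by the reference category (default: of the patients whose measured
LDL-C lies in a bin, how many were estimated into that bin) or by the
estimated category; both orientations share the same overall proportion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

DEFAULT_EDGES = (40.0, 55.0, 70.0, 100.0, 130.0, 160.0, 190.0)
DEFAULT_LABELS = ("<40", "40-54", "55-69", "70-99", "100-129",
                  "130-159", "160-189", ">=190")


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered cut-points defining len(edges)+1 half-open bins."""

    edges: tuple[float, ...] = DEFAULT_EDGES
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        if len(self.labels) != len(self.edges) + 1:
            raise ValidationError("need exactly one label per bin")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("category edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def default_scheme() -> CategoryScheme:
    return CategoryScheme()


def categorize(ldl, scheme: CategoryScheme | None = None):
    """Map LDL-C (mg/dL) to a bin index 0..n_bins−1; non-decreasing in ldl."""
    scheme = scheme or default_scheme()
    arr = np.asarray(ldl, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("categorize requires finite LDL-C values")
    idx = np.searchsorted(np.asarray(scheme.edges), arr, side="right")
    return int(idx) if idx.ndim == 0 else idx


@dataclass(frozen=True)
class ConcordanceResult:
    """Overall and per-category agreement proportions.

    ``per_category[k]`` is the agreement proportion within stratum k of the
    chosen orientation (NaN where the stratum is empty); ``denominators[k]``
    is that stratum's size.
    """

    overall: float
    per_category: np.ndarray
    denominators: np.ndarray
    orientation: str
    n: int
    labels: tuple[str, ...]


def concordance(
    estimates,
    references,
    scheme: CategoryScheme | None = None,
    *,
    by: str = "reference",
) -> ConcordanceResult:
    """Category agreement between paired estimated and reference LDL-C.

    *by* selects the per-category stratification: ``"reference"`` (default)
    or ``"estimate"``. Raises on empty or length-mismatched input.
    """
    scheme = scheme or default_scheme()
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValidationError("estimates and references must have equal length")
    if est.size == 0:
        raise ValidationError("concordance requires non-empty input")
    if by not in ("reference", "estimate"):
        raise ValidationError("orientation must be 'reference' or 'estimate'")

    cat_e = categorize(est, scheme)
    cat_r = categorize(ref, scheme)
    agree = cat_e == cat_r
    strat = cat_r if by == "reference" else cat_e
    k = scheme.n_bins
    denom = np.bincount(strat, minlength=k).astype(float)
    hits = np.bincount(strat, weights=agree, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cat = np.where(denom > 0, hits / denom, np.nan)
    return ConcordanceResult(
        overall=float(np.mean(agree)),
        per_category=per_cat,
        denominators=denom.astype(int),
        orientation=by,
        n=int(est.size),
        labels=scheme.labels,
    )
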