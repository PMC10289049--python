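"""Reading and writing cohort tables (delimited text).

Input is delimited text with a header; required columns are tc, hdl and tg
(mg/dL), with optional ldl_ref, vldl, lpa_c and covariates. A column mapping
can rename arbitrary headers onto the canonical names. Every input row is
accounted for: records failing validation are counted per rejection reason,
never silently dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .exceptions import ValidationError
from .panel import validate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortReadResult:
    """Accepted records plus per-reason rejection counts."""

    frame: pd.DataFrame
    rejections: Mapping[str, int]

    @property
    def n_accepted(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())


def read_cohort(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    require_reference: bool = False,
    sep: str = ",",
) -> CohortReadResult:
    """Read and validate a cohort from delimited text.

    *column_map* maps file headers to canonical names, e.g.
    ``{"CHOL": "tc"}``. Raises :class:`ValidationError` when a required
    column is absent after mapping.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise ValidationError(f"cannot read cohort file {path}: {exc}") from exc
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    accepted, rejected = validate_cohort(raw, require_reference=require_reference)
    logger.info(
        "read %s: %d accepted, %d rejected (%s)",
        path, len(accepted), sum(rejected.values()),
        dict(rejected) or "no rejections",
    )
    return CohortReadResult(frame=accepted, rejections=dict(rejected))


def write_cohort(
    frame: pd.DataFrame,
    path: str | Path,
    *,
    metadata: Mapping | None = None,
) -> None:
    """Write a cohort as CSV at full precision.

    When *metadata* is given (e.g. generator config and seed), a YAML
    sidecar ``<path>.meta.yaml`` records it for provenance.
    """
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.17g")
    if metadata is not None:
        sidecar = path.with_name(path.name + ".meta.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(dict(metadata), fh, sort_keys=False)
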