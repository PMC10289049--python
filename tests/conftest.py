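"""Shared fixtures: seeded random panels and a small hand-checkable cohort."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_random_panels(n: int, seed: int, tg_max: float = 399.0):
    """Seeded random (tc, hdl, tg) arrays spanning the clinical range."""
    rng = np.random.default_rng(seed)
    hdl = rng.uniform(20, 100, n)
    non_hdl = rng.uniform(40, 300, n)
    tg = rng.uniform(10, tg_max, n)
    return hdl + non_hdl, hdl, tg  # tc, hdl, tg with tc > hdl always


@pytest.fixture
def random_panels():
    return make_random_panels


@pytest.fixture
def twenty_record_cohort() -> pd.DataFrame:
    """20 fixed records with reference LDL-C spanning all 8 categories.

    Values are plain numbers chosen by hand so category assignments, medians
    and reclassification counts can be tallied with a naive loop.
    """
    tc = [150, 160, 180, 190, 200, 210, 215, 220, 230, 240,
          250, 255, 260, 270, 280, 150, 170, 300, 310, 320]
    hdl = [60, 55, 50, 58, 52, 48, 55, 60, 45, 50,
           55, 40, 42, 44, 46, 70, 80, 50, 55, 40]
    tg = [80, 120, 150, 90, 110, 130, 160, 200, 140, 180,
          100, 220, 250, 300, 350, 60, 90, 120, 140, 160]
    ldl_ref = [35, 50, 66, 105, 120, 135, 128, 110, 158, 162,
               170, 172, 190, 205, 210, 68, 71, 225, 230, 248]
    frame = pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg,
                          "ldl_ref": [float(x) for x in ldl_ref]})
    frame[["tc", "hdl", "tg"]] = frame[["tc", "hdl", "tg"]].astype(float)
    frame["non_hdl"] = frame["tc"] - frame["hdl"]
    return frame


@pytest.fixture
def small_cohort():
    """A modest synthetic cohort reused across tests (cheap to build)."""
    from ldlkit import generate_cohort

    return generate_cohort(n=5000, seed=123)
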