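"""Upward-reclassification counting at the 70 mg/dL treatment cutpoint."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ldlkit import generate_cohort, upward_reclassification
from ldlkit.exceptions import ValidationError


class TestCounting:
    def test_friedewald_never_reclassifies_itself(self, small_cohort):
        res = upward_reclassification(small_cohort, "friedewald")
        assert res.denominator > 0
        assert res.correct == 0 and res.proportion == 0.0

    def test_three_panel_hand_evaluation(self):
        # invert LDL = TC − HDL − TG/5 so Friedewald gives exactly {60, 65, 90};
        # the alternative (Chen) then gives {78, 82.5, 105}; refs {75, 60, 96}
        # → denominator 2 (the 60 and 65), numerator 1 (60→78 with ref 75)
        tg = np.full(3, 300.0)
        hdl = np.full(3, 50.0)
        fried = np.array([60.0, 65.0, 90.0])
        tc = fried + hdl + tg / 5
        cohort = pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg,
                               "ldl_ref": [75.0, 60.0, 96.0]})
        res = upward_reclassification(cohort, "chen")
        np.testing.assert_allclose(0.9 * tc - 0.9 * hdl - 0.1 * tg,
                                   [78.0, 82.5, 105.0])
        assert (res.denominator, res.correct, res.incorrect) == (2, 1, 1)
        assert res.proportion == pytest.approx(0.5)

    def test_cutpoint_boundary_is_at_or_above(self):
        # alternative estimate and reference both exactly 70 count as upward
        tg = np.array([100.0])
        hdl = np.array([50.0])
        # chen estimate = 0.9*tc - 45 - 10 = 70 → tc = 125/0.9
        tc = np.array([125.0 / 0.9])
        fried = tc - hdl - tg / 5
        assert fried[0] < 70
        cohort = pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg,
                               "ldl_ref": [70.0]})
        res = upward_reclassification(cohort, "chen")
        assert (res.denominator, res.correct) == (1, 1)

    def test_incorrect_reclassifications_reported_separately(self):
        tg = np.full(4, 150.0)
        hdl = np.full(4, 45.0)
        fried = np.array([60.0, 62.0, 64.0, 90.0])
        tc = fried + hdl + tg / 5
        cohort = pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg,
                               "ldl_ref": [75.0, 50.0, 72.0, 95.0]})
        res = upward_reclassification(cohort, "martin_hopkins")
        assert res.denominator == 3
        assert res.correct + res.incorrect <= res.denominator
        assert res.incorrect >= 0

    def test_missing_reference_raises(self, small_cohort):
        broken = small_cohort.copy()
        broken.loc[broken.index[0], "ldl_ref"] = np.nan
        with pytest.raises(ValidationError, match="ldl_ref"):
            upward_reclassification(broken, "martin_hopkins")

    def test_empty_denominator_is_flagged_not_raised(self):
        cohort = pd.DataFrame({"tc": [300.0], "hdl": [50.0], "tg": [100.0],
                               "ldl_ref": [220.0]})
        res = upward_reclassification(cohort, "martin_hopkins")
        assert not res.defined
        assert np.isnan(res.proportion)


class TestProperties:
    def test_counts_bounded_by_cohort_size(self, small_cohort):
        res = upward_reclassification(small_cohort, "martin_hopkins")
        assert 0 <= res.correct <= res.denominator <= len(small_cohort)
        assert 0 <= res.proportion <= 1

    def test_restricting_tg_range_never_grows_the_denominator(self, small_cohort):
        full = upward_reclassification(small_cohort, "martin_hopkins",
                                       tg_range=(0, 400))
        narrow = upward_reclassification(small_cohort, "martin_hopkins",
                                         tg_range=(150, 400))
        assert narrow.denominator <= full.denominator
        assert narrow.correct <= full.correct

    def test_reclassification_concentrates_at_high_tg(self):
        """With ratio heterogeneity rising with TG, the 150–399 stratum shows
        more confirmed upward reclassification than TG < 400 overall."""
        cohort = generate_cohort(n=60_000, seed=2024)
        full = upward_reclassification(cohort, "martin_hopkins",
                                       tg_range=(0, 400))
        high = upward_reclassification(cohort, "martin_hopkins",
                                       tg_range=(150, 400))
        assert high.defined and full.defined
        assert high.proportion > full.proportion
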