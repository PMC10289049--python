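"""Synthetic cohort generator: identities, calibration and reproducibility."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ldlkit import GeneratorConfig, generate_cohort, lognormal_params_from_quantiles
from ldlkit.exceptions import ValidationError

Z75 = float(stats.norm.ppf(0.75))


class TestQuantileParameterization:
    def test_geometric_symmetry_case(self):
        loc, scale = lognormal_params_from_quantiles(100, 50, 200)
        assert loc == pytest.approx(math.log(100))
        assert scale == pytest.approx(math.log(4) / (2 * Z75))

    def test_round_trip_sampling_recovers_median_and_iqr(self):
        loc, scale = lognormal_params_from_quantiles(114, 81, 164)
        rng = np.random.default_rng(5)
        x = rng.lognormal(loc, scale, 1_000_000)
        assert np.median(x) == pytest.approx(114, rel=0.005)
        q25, q75 = np.quantile(x, [0.25, 0.75])
        # asymmetric request: the averaged scale reproduces the IQR ratio
        assert q75 / q25 == pytest.approx(164 / 81, rel=0.01)

    def test_near_degenerate_quantiles_collapse_to_constant(self):
        loc, scale = lognormal_params_from_quantiles(100, 99.9999, 100.0001)
        assert scale == pytest.approx(0.0, abs=1e-5)
        rng = np.random.default_rng(0)
        x = rng.lognormal(loc, scale, 100)
        assert np.allclose(x, 100, rtol=1e-4)

    @pytest.mark.parametrize("bad", [(0, 50, 200), (100, 200, 300),
                                     (100, 50, 90), (-5, 1, 2)])
    def test_non_monotone_or_non_positive_quantiles_raise(self, bad):
        with pytest.raises(ValidationError):
            lognormal_params_from_quantiles(*bad)


class TestConstructionIdentities:
    def test_cholesterol_accounting_identity(self, small_cohort):
        residual = (small_cohort.tc - small_cohort.hdl - small_cohort.vldl
                    - small_cohort.lpa_c - small_cohort.ldl_ref)
        assert np.abs(residual).max() < 1e-9

    def test_ratio_identity_and_bounds(self, small_cohort):
        ratio = small_cohort.tg / small_cohort.vldl
        assert np.abs(small_cohort.vldl * ratio - small_cohort.tg).max() < 1e-9
        assert ratio.min() >= 3.0 - 1e-12 and ratio.max() <= 13.0 + 1e-12

    def test_non_hdl_is_derived(self, small_cohort):
        assert np.array_equal(small_cohort.non_hdl,
                              small_cohort.tc - small_cohort.hdl)


class TestReproducibilityAndCalibration:
    def test_identical_seed_gives_identical_cohort(self):
        a = generate_cohort(n=2000, seed=99)
        b = generate_cohort(n=2000, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort(n=2000, seed=99)
        b = generate_cohort(n=2000, seed=100)
        assert not np.array_equal(a.tg.to_numpy(), b.tg.to_numpy())

    def test_medians_converge_to_configured_values(self):
        cohort = generate_cohort(n=40_000, seed=77)
        config = GeneratorConfig()
        for col, triple in [("tg", config.tg), ("hdl", config.hdl),
                            ("ldl_ref", config.ldl), ("lpa_c", config.lpa_c)]:
            assert np.median(cohort[col]) == pytest.approx(
                triple.median, rel=0.02
            ), col
        assert np.median(cohort.tg / cohort.vldl) == pytest.approx(5.0, rel=0.02)

    def test_covariate_proportions(self):
        cohort = generate_cohort(n=40_000, seed=78)
        assert (cohort.sex == "female").mean() == pytest.approx(0.537, abs=0.01)
        assert (cohort.fasting == "fasting").mean() == pytest.approx(0.194, abs=0.01)
        assert (cohort.fasting == "unknown").mean() == pytest.approx(0.687, abs=0.01)
        assert cohort.age.isna().mean() == pytest.approx(0.007, abs=0.005)

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            GeneratorConfig(n=0)
        with pytest.raises(Exception):
            GeneratorConfig(fasting_props={"fasting": 0.6, "non_fasting": 0.6,
                                           "unknown": 0.1})
        with pytest.raises(Exception):
            GeneratorConfig(ratio_bounds=(0.0, 13.0))


class TestMechanism:
    def test_friedewald_error_trends_negative_with_tg_at_low_ldl(self):
        """The TG:VLDL-C ratio rising with TG makes Friedewald's fixed /5
        increasingly overestimate VLDL-C — its LDL error turns negative with
        rising TG among low-LDL records."""
        cohort = generate_cohort(n=30_000, seed=5)
        sub = cohort[(cohort.ldl_ref < 100) & (cohort.tg < 400)]
        from ldlkit import estimate_ldl

        err = estimate_ldl(sub, "friedewald") - sub["ldl_ref"].to_numpy()
        rho, p = stats.spearmanr(sub["tg"].to_numpy(), err)
        assert rho < 0 and p < 0.01
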