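"""Equation registry structure and the estimation engine's closed forms."""
from __future__ import annotations

import numpy as np
import pytest

from ldlkit import (
    LipidPanel,
    TGDomainError,
    UnknownEquationError,
    default_registry,
    estimate_ldl,
)
from ldlkit.registry import FAMILIES

from .conftest import make_random_panels
from . import oracle

REGISTRY = default_registry()


class TestRegistryStructure:
    def test_exactly_23_primary_plus_extended_variant(self):
        assert len(REGISTRY.primary_ids()) == 23
        assert len(REGISTRY) == 24
        assert "martin_hopkins_extended" in REGISTRY.ids()
        assert "martin_hopkins_extended" not in REGISTRY.primary_ids()

    def test_every_family_is_one_of_the_four(self):
        assert {d.family for d in REGISTRY} <= set(FAMILIES)

    def test_family_census_matches_the_literature_classes(self):
        census = {f: sum(d.family == f and d.role == "primary" for d in REGISTRY)
                  for f in FAMILIES}
        assert census == {"fixed_ratio": 7, "linear": 13,
                          "table_factor": 1, "quadratic": 2}

    def test_fixed_ratio_divisors_positive(self):
        for d in REGISTRY:
            if d.family == "fixed_ratio":
                assert d.coefficients["k"] > 0

    def test_unknown_id_raises_with_known_ids(self):
        with pytest.raises(UnknownEquationError, match="friedewald"):
            REGISTRY["friedewld"]


class TestClosedForms:
    @pytest.mark.parametrize(
        "eq_id,expected",
        [("friedewald", 130.0), ("chen", 125.0), ("cordova", 112.5)],
    )
    def test_published_worked_examples(self, eq_id, expected):
        assert estimate_ldl(LipidPanel(200, 50, 100), eq_id) == pytest.approx(
            expected, abs=1e-12
        )

    def test_sampson_matches_independent_transcription(self):
        got = estimate_ldl((200.0, 50.0, 100.0), "sampson")
        assert got == pytest.approx(oracle.sampson(200.0, 50.0, 100.0), abs=1e-9)

    def test_accepts_panel_mapping_and_tuple_inputs(self, twenty_record_cohort):
        frame = twenty_record_cohort
        via_frame = estimate_ldl(frame, "friedewald")
        via_tuple = estimate_ldl(
            (frame["tc"].to_numpy(), frame["hdl"].to_numpy(),
             frame["tg"].to_numpy()),
            "friedewald",
        )
        np.testing.assert_array_equal(via_frame, via_tuple)

    def test_negative_estimates_are_returned_unclipped(self):
        # very high TG relative to non-HDL forces Friedewald negative
        assert estimate_ldl((100.0, 40.0, 390.0), "friedewald") < 0

    def test_tg_outside_domain_raises_with_equation_and_value(self):
        with pytest.raises(TGDomainError, match=r"friedewald.*450|450.*friedewald"):
            estimate_ldl((200.0, 50.0, 450.0), "friedewald")

    def test_domain_override_allows_research_use(self):
        got = estimate_ldl((200.0, 50.0, 450.0), "friedewald",
                           override_tg_domain=True)
        assert got == pytest.approx(200 - 50 - 90, abs=1e-12)

    def test_mmol_published_equation_converted_once(self):
        # dansethakul ships in mmol/L; engine output must equal convert-in /
        # evaluate / convert-out by hand
        tc, hdl, tg = 200.0, 50.0, 100.0
        assert estimate_ldl((tc, hdl, tg), "dansethakul") == pytest.approx(
            oracle.dansethakul(tc, hdl, tg), abs=1e-9
        )


class TestFamilyInvariants:
    def test_fixed_ratio_conservation(self):
        """estimate + hdl + tg/k recovers tc exactly for the whole family."""
        tc, hdl, tg = make_random_panels(500, seed=11)
        for d in REGISTRY:
            if d.family != "fixed_ratio":
                continue
            est = estimate_ldl((tc, hdl, tg), d)
            np.testing.assert_allclose(
                est + hdl + tg / d.coefficients["k"], tc, rtol=0, atol=1e-9
            )

    def test_fixed_ratio_strictly_decreasing_in_tg(self):
        tg = np.linspace(10, 399, 200)
        for d in REGISTRY:
            if d.family != "fixed_ratio":
                continue
            est = estimate_ldl((np.full_like(tg, 200.0),
                                np.full_like(tg, 50.0), tg), d)
            assert np.all(np.diff(est) < 0), d.id

    @pytest.mark.parametrize("eq_id", ["chen", "cordova"])
    def test_zero_intercept_linear_equations_are_homogeneous(self, eq_id):
        tc, hdl, tg = make_random_panels(200, seed=12)
        for lam in (0.5, 2.0):
            scaled = estimate_ldl((lam * tc, lam * hdl, lam * tg), eq_id,
                                  override_tg_domain=True)
            base = estimate_ldl((tc, hdl, tg), eq_id, override_tg_domain=True)
            np.testing.assert_allclose(scaled, lam * base, rtol=1e-12)
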