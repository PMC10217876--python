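"""Pollution/risk index formulas, classification, and orchestration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrisk.data import SamplePanel, ToxicityTables
from sedrisk.indices import (
    ClassificationScheme,
    DomainError,
    classify,
    compute_all,
    default_schemes,
    ef,
    eri,
    igeo,
    igeo_class,
    ri,
    spi,
    tri,
    tri_i,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False)


class TestIgeo:
    def test_background_times_1p5_is_zero(self):
        assert igeo(1.5 * 4.0, 4.0) == pytest.approx(0.0)

    def test_three_times_background_is_one(self):
        assert igeo(3 * 4.0, 4.0) == pytest.approx(1.0)

    def test_median_cr_against_mean_background(self):
        # log2(7.78 / (1.5 * 4.74)) = log2(7.78 / 7.11)
        assert igeo(7.78, 4.74) == pytest.approx(math.log2(7.78 / 7.11), abs=1e-12)
        assert igeo(7.78, 4.74) == pytest.approx(0.1300, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            igeo(0.0, 1.0)
        with pytest.raises(DomainError):
            igeo(1.0, -1.0)

    @given(c=positive, gb=positive)
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_concentration(self, c, gb):
        assert igeo(2 * c, gb) > igeo(c, gb)
        assert igeo(c, 2 * gb) < igeo(c, gb)


class TestIgeoClass:
    @pytest.mark.parametrize(
        "value,expected",
        [(-2.3, 0), (0.0, 0), (0.5, 1), (1.0, 1), (2.5, 3), (5.0, 5), (5.01, 6), (9.9, 6)],
    )
    def test_mueller_grades(self, value, expected):
        assert igeo_class(value) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            igeo_class(float("nan"))


class TestEF:
    def test_identity_when_ratios_match(self):
        assert ef(2.0, 2.0, 7000.0, 7000.0) == pytest.approx(1.0)

    def test_double_metal_ratio(self):
        assert ef(4.0, 2.0, 7000.0, 7000.0) == pytest.approx(2.0)

    def test_iron_enrichment_halves(self):
        assert ef(4.0, 2.0, 28000.0, 7000.0) == pytest.approx(0.5)


class TestSpiEriRi:
    def test_spi_at_background_is_one(self):
        assert spi(5.49, 5.49) == pytest.approx(1.0)

    def test_spi_mean_cu_over_background(self):
        assert spi(29.23, 5.49) == pytest.approx(5.3242, abs=5e-5)

    @pytest.mark.parametrize(
        "analyte,expected",
        [("As", 10), ("Cd", 30), ("Co", 5), ("Cr", 2), ("Cu", 5),
         ("Hg", 40), ("Mn", 1), ("Ni", 5), ("Pb", 5), ("Zn", 1)],
    )
    def test_eri_at_unit_spi_equals_toxic_response(self, analyte, expected):
        assert eri(analyte, 1.0) == pytest.approx(expected)

    def test_eri_mn_scales_linearly(self):
        assert eri("Mn", 2.5) == pytest.approx(2.5)

    def test_eri_unknown_metal_rejected(self):
        with pytest.raises(DomainError):
            eri("Fe", 1.0)

    def test_ri_all_metals_at_background_is_104(self):
        values = {a: eri(a, 1.0) for a in ToxicityTables().tri_coeff}
        total, complete = ri(values)
        assert total == pytest.approx(104.0)
        assert complete

    def test_ri_partial_flagged_incomplete(self):
        total, complete = ri({"Cd": 30.0})
        assert total == pytest.approx(30.0) and not complete

    def test_ri_empty_rejected(self):
        with pytest.raises(DomainError):
            ri({})


class TestTRI:
    def test_zero_concentration_is_zero(self):
        assert tri_i(0.0, 0.68, 4.2) == 0.0

    def test_rms_at_cd_tel(self):
        # C = TEL for Cd: sqrt((1 + (0.68/4.2)^2) / 2)
        assert tri_i(0.68, 0.68, 4.2) == pytest.approx(
            math.sqrt((1 + (0.68 / 4.2) ** 2) / 2), rel=1e-12
        )
        assert tri_i(0.68, 0.68, 4.2) == pytest.approx(0.7163, abs=5e-5)

    def test_equal_tel_pel_limit_is_one(self):
        # precondition-relaxed sanity: both ratios 1 -> RMS 1
        eps = 1e-9
        assert tri_i(1.0, 1.0, 1.0 + eps) == pytest.approx(1.0, abs=1e-6)

    def test_inverted_guideline_rejected(self):
        from sedrisk.data import ValidationError

        with pytest.raises(ValidationError):
            tri_i(1.0, 4.2, 0.68)

    def test_tri_sums_components(self):
        rng = np.random.default_rng(3)
        tox = ToxicityTables()
        parts = {a: tri_i(rng.uniform(0, 100), *tox.guidelines[a]) for a in tox.guidelines}
        total, complete = tri(parts)
        assert total == pytest.approx(sum(parts.values()), rel=1e-12)
        assert complete

    def test_single_component(self):
        total, complete = tri({"Cd": 0.7164})
        assert total == pytest.approx(0.7164) and not complete

    @given(c=positive)
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_concentration(self, c):
        assert tri_i(2 * c, 0.68, 4.2) > tri_i(c, 0.68, 4.2)


class TestClassify:
    @pytest.mark.parametrize(
        "index,value,expected_label",
        [
            ("RI", 149.99, "low"),
            ("RI", 150.0, "moderate"),
            ("RI", 299.99, "moderate"),
            ("TRI", 20.01, "very high"),
            ("Eri", 80.0, "considerable"),
            ("Eri", 79.99, "moderate"),
            ("EF", 1.99, "minimal"),
        ],
    )
    def test_anchor_boundaries(self, index, value, expected_label):
        _, label = classify(index, value)
        assert label == expected_label

    def test_unknown_index_rejected(self):
        with pytest.raises(DomainError):
            classify("PLI", 1.0)

    def test_breakpoints_must_increase(self):
        from sedrisk.data import ValidationError

        with pytest.raises(ValidationError):
            ClassificationScheme("X", (5.0, 5.0), ("a", "b", "c"))


class TestComputeAll:
    def test_all_at_background(self, tiny_panel, tiny_gb):
        res = compute_all(tiny_panel, tiny_gb)
        igeo_rows = res[res["index"] == "Igeo"]
        assert np.allclose(igeo_rows["value"], math.log2(1 / 1.5))
        assert (igeo_rows["class"] == 0).all()
        ef_rows = res[res["index"] == "EF"]
        assert len(ef_rows) == 10 and np.allclose(ef_rows["value"], 1.0)
        ri_row = res[res["index"] == "RI"]
        assert ri_row["value"].iloc[0] == pytest.approx(104.0)
        assert ri_row["analyte"].iloc[0] == "ALL"
        assert ri_row["label"].iloc[0] == "low"

    def test_panel_without_fe_has_no_ef_rows(self, tiny_panel, tiny_gb):
        panel = SamplePanel(tiny_panel.data[tiny_panel.data["analyte"] != "Fe"])
        res = compute_all(panel, tiny_gb)
        assert not (res["index"] == "EF").any()
        assert (res["index"] == "Igeo").sum() == 10

    def test_empty_panel_gives_empty_result(self, tiny_gb):
        panel = SamplePanel(
            pd.DataFrame(columns=["site_id", "year", "analyte", "value", "flag"])
        )
        assert len(compute_all(panel, tiny_gb)) == 0

    def test_missing_background_listed(self, tiny_panel):
        from sedrisk.data import GBTable, ValidationError

        gb = GBTable({(1, "As"): 2.0})
        with pytest.raises(ValidationError, match="Cd"):
            compute_all(tiny_panel, gb)


class TestScaleProperties:
    def test_doubling_everything_preserves_ratio_indices_but_not_tri(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            c, g, cfe, gfe = rng.uniform(0.1, 100, 4)
            assert igeo(2 * c, 2 * g) == pytest.approx(igeo(c, g), rel=1e-12)
            assert ef(2 * c, 2 * g, 2 * cfe, 2 * gfe) == pytest.approx(ef(c, g, cfe, gfe), rel=1e-12)
            assert spi(2 * c, 2 * g) == pytest.approx(spi(c, g), rel=1e-12)
            assert tri_i(2 * c, 0.68, 4.2) != pytest.approx(tri_i(c, 0.68, 4.2), rel=1e-6)
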