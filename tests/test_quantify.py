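import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadquant.quantify import (
    QuantResult,
    SamplePrep,
    corrected_pmol,
    effective_analyzed_volume,
    intracellular_volume,
    isotope_dilution_pmol,
    od_normalized_volume,
    report,
    resuspension_volume,
    round_sig,
    to_concentration,
)


class TestVolumes:
    def test_reference_pellet_resuspends_in_100ul(self):
        assert resuspension_volume(3.6) == pytest.approx(100.0)

    def test_resuspension_scales_linearly(self):
        assert resuspension_volume(7.2) == pytest.approx(200.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            resuspension_volume(0.0)

    @pytest.mark.parametrize(
        "od,expected,warned",
        [(14.0, 100.0, False), (28.0, 200.0, False), (10.0, 100.0, True)],
    )
    def test_od_normalization(self, od, expected, warned):
        volume, flag = od_normalized_volume(100.0, od)
        assert volume == pytest.approx(expected)
        assert flag is warned

    def test_yeast_intracellular_volume(self):
        # 3e7 cells x 70 fl = 2.1 ul
        assert intracellular_volume(3e7, 70.0, unit="fl") == pytest.approx(2.1)

    def test_mammalian_intracellular_volume(self):
        assert intracellular_volume(4e6, 2.5, unit="pl") == pytest.approx(10.0)

    def test_zero_cells(self):
        assert intracellular_volume(0, 70.0) == 0.0

    def test_unit_declaration_is_respected(self):
        assert intracellular_volume(1e6, 2.5, unit="pl") == pytest.approx(
            intracellular_volume(1e6, 2500.0, unit="fl")
        )

    def test_effective_volume_worked_example(self):
        # 1.25 ul analyzed of 100 ul holding 2.1 ul of cell water -> 26.25 nl
        prep = SamplePrep(cell_count=3e7, per_cell_volume_fl=70.0)
        eff = effective_analyzed_volume(2.1, 100.0, prep)
        assert eff == pytest.approx(26.25)
        assert round_sig(eff) == pytest.approx(26.0)

    def test_effective_volume_inverse_in_final_volume(self):
        prep = SamplePrep(cell_count=3e7)
        assert effective_analyzed_volume(2.1, 200.0, prep) == pytest.approx(
            effective_analyzed_volume(2.1, 100.0, prep) / 2
        )

    def test_analyzing_more_than_the_sample_rejected(self):
        prep = SamplePrep(cell_count=3e7)
        with pytest.raises(ValueError):
            effective_analyzed_volume(2.1, 1.0, prep)


class TestIsotopeDilution:
    def test_equal_areas_return_the_heavy_amount(self):
        assert isotope_dilution_pmol(500.0, 500.0, 5.0) == pytest.approx(5.0)

    def test_linear_in_the_ratio(self):
        assert isotope_dilution_pmol(1000.0, 500.0, 5.0) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        light=st.floats(1.0, 1e6),
        heavy=st.floats(1.0, 1e6),
        pmol=st.floats(1e-3, 1e3),
        suppression=st.floats(1e-3, 1.0),
    )
    def test_shared_suppression_cancels_exactly(self, light, heavy, pmol, suppression):
        base = isotope_dilution_pmol(light, heavy, pmol)
        suppressed = isotope_dilution_pmol(light * suppression, heavy * suppression, pmol)
        assert suppressed == pytest.approx(base, rel=1e-12)

    def test_missing_heavy_peak_rejected(self):
        with pytest.raises(ValueError):
            isotope_dilution_pmol(100.0, 0.0, 5.0)

    def test_unity_correction_factor_reduces_to_plain_ratio(self):
        assert corrected_pmol(300.0, 150.0, 5.0, cf=1.0) == pytest.approx(
            isotope_dilution_pmol(300.0, 150.0, 5.0)
        )

    def test_correction_factor_divides(self):
        assert corrected_pmol(300.0, 150.0, 5.0, cf=2.0) == pytest.approx(5.0)


class TestConcentration:
    def test_zero_pmol(self):
        assert to_concentration(0.0, 26.0) == 0.0

    def test_unit_identity(self):
        # 1 pmol in 1 ul (= 1000 nl) is 1 uM
        assert to_concentration(1.0, 1000.0) == pytest.approx(1.0)

    def test_worked_example(self):
        assert to_concentration(6.76, 26.0) == pytest.approx(260.0)


def quant(name, conc, flag="ok", bound=math.nan):
    return QuantResult(metabolite=name, conc_um=conc, flag=flag, loq_bound_um=bound)


class TestReport:
    def results(self):
        return [
            quant("NAD", 260.0),
            quant("NADH", 6.7),
            quant("NADP", 57.0),
            quant("Nam", 39.0),
            quant("NA", math.nan, flag="below_loq", bound=4.0),
            quant("NADPH", math.nan, flag="excluded"),
        ]

    def test_summary_ratios(self):
        table = report(self.results())
        by_name = dict(zip(table.metabolite, table.reported))
        assert by_name["NAD/NADH"] == "39"
        assert by_name["NAD/NADP"] == "4.6"

    def test_below_loq_rendered_as_bound(self):
        table = report(self.results())
        by_name = dict(zip(table.metabolite, table.reported))
        assert by_name["NA"] == "<4"

    def test_excluded_metabolites_never_reported(self):
        table = report(self.results())
        assert "NADPH" not in set(table.metabolite)
        assert "AMP" not in set(table.metabolite)

    def test_nadp_carries_caveat(self):
        table = report(self.results())
        notes = table.loc[table.metabolite == "NADP", "notes"].iloc[0]
        assert "NADPH" in notes

    def test_two_significant_figure_rounding(self):
        table = report([quant("NAD", 263.7), quant("NADH", 6.74)])
        by_name = dict(zip(table.metabolite, table.reported))
        assert by_name["NAD"] == "260"
        assert by_name["NADH"] == "6.7"
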