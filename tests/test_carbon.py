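"""Carbon-closure accounting: the CO2 equation and the per-strain ledger."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from pyroflux.calibration import MeasurementSet
from pyroflux.carbon import (
    AccountingError,
    CarbonSpec,
    EstimationCoefficients,
    carbon_ledger,
    co2_from_products,
)

concs = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def _prop_measurements():
    """Printed endpoint table for the producing strain and its AdhF knockout."""
    prop = MeasurementSet(
        strain="PROP", cellobiose_consumed=6.8, protein_yield=93.65,
        endpoint_products={"1-propanol": 0.40, "propionate": 0.63,
                           "ethanol": 9.36, "acetate": 6.26, "acetoin": 0.0})
    dadhf = MeasurementSet(
        strain="PROP-dAdhF", cellobiose_consumed=7.0, protein_yield=93.65,
        endpoint_products={"1-propanol": 0.49, "propionate": 0.90,
                           "ethanol": 8.98, "acetate": 7.49, "acetoin": 0.0})
    return prop, dadhf


class TestCo2Equation:
    @pytest.mark.parametrize("acetate,ethanol,acetoin,expected", [
        (6.26, 9.36, 0.0, 15.62),
        (0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 2.0),
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 1.0, 0.0, 1.0),
    ])
    def test_coefficient_structure(self, acetate, ethanol, acetoin, expected):
        assert co2_from_products(acetate, ethanol, acetoin) == \
               pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(acetate=concs, ethanol=concs, acetoin=concs)
    def test_linearity(self, acetate, ethanol, acetoin):
        assert co2_from_products(acetate, ethanol, acetoin) == \
               pytest.approx(acetate + ethanol + 2 * acetoin, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            co2_from_products(-0.1, 0.0, 0.0)


class TestCarbonLedger:
    def test_printed_percentages_recovered(self):
        prop, dadhf = _prop_measurements()
        printed = {
            "PROP": {"1-propanol": 1.4, "propionate": 2.3, "ethanol": 22.7,
                     "acetate": 15.2, "CO2": 19.1},
            "PROP-dAdhF": {"1-propanol": 1.7, "propionate": 3.3,
                           "ethanol": 21.1, "acetate": 17.9, "CO2": 19.6},
        }
        for meas in (prop, dadhf):
            ledger = carbon_ledger(meas)
            for compound, expected in printed[meas.strain].items():
                assert ledger.percent_of(compound) == \
                       pytest.approx(expected, abs=0.3), (meas.strain, compound)

    def test_additivity(self):
        prop, _ = _prop_measurements()
        ledger = carbon_ledger(prop)
        assert ledger.total_percent == pytest.approx(
            sum(e.percent for e in ledger.entries), rel=1e-9)

    def test_basis_invariance_under_scaling(self):
        prop, _ = _prop_measurements()
        scaled = dataclasses.replace(
            prop, cellobiose_consumed=3 * prop.cellobiose_consumed,
            endpoint_products={c: 3 * v
                               for c, v in prop.endpoint_products.items()})
        a, b = carbon_ledger(prop), carbon_ledger(scaled)
        for entry in a.entries:
            assert b.percent_of(entry.compound) == \
                   pytest.approx(entry.percent, rel=1e-12)

    def test_removing_ethanol_lowers_co2_by_its_mm(self):
        prop, _ = _prop_measurements()
        without = dataclasses.replace(
            prop, endpoint_products={**prop.endpoint_products, "ethanol": 0.0})
        a, b = carbon_ledger(prop), carbon_ledger(without)
        ethanol_mm = prop.product("ethanol")
        co2_atoms = CarbonSpec().atoms_of("CO2")
        delta = (a.percent_of("CO2") - b.percent_of("CO2"))
        assert delta * a.consumed_mm_carbon / 100 == \
               pytest.approx(ethanol_mm * co2_atoms, rel=1e-9)

    def test_zero_products_zero_coefficients_total_zero(self):
        meas = MeasurementSet(strain="X", cellobiose_consumed=5.0,
                              endpoint_products={})
        assert carbon_ledger(meas).total_percent == 0.0

    def test_unknown_compound_is_named(self):
        meas = MeasurementSet(strain="X", cellobiose_consumed=5.0,
                              endpoint_products={"levulinate": 1.0})
        with pytest.raises(AccountingError, match="levulinate"):
            carbon_ledger(meas)

    def test_estimated_sinks_appear_only_with_coefficients(self):
        prop, _ = _prop_measurements()
        plain = carbon_ledger(prop)
        assert all(e.compound != "biomass" for e in plain.entries)
        coeffs = EstimationCoefficients(biomass_carbon_per_protein=0.1,
                                        alanine_per_cellobiose=0.02)
        rich = carbon_ledger(prop, coeffs=coeffs)
        assert rich.percent_of("biomass") == pytest.approx(
            0.1 * prop.protein_yield / plain.consumed_mm_carbon * 100)
        assert rich.percent_of("alanine") == pytest.approx(
            0.02 * prop.cellobiose_consumed * 3
            / plain.consumed_mm_carbon * 100)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            EstimationCoefficients(dip_per_protein=-1.0)

    def test_invalid_carbon_spec_rejected(self):
        with pytest.raises(ValueError):
            CarbonSpec(atoms={"ethanol": 0})
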