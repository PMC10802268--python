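"""Parameter registry: unit conversion, baseline models, perturbations."""

import dataclasses
import math

import pytest

import ccmrd
from ccmrd.params import (TABLE1, ParameterSet, equilibrium_dic,
                          hplus_micromolar, perturb_ensemble,
                          perturb_parameters, scenario_grid)


class TestUnitConversion:
    @pytest.mark.parametrize("value,unit,expected", [
        (0.35, "cm/s", 3500.0),
        (3.2e-2, "m/s", 32000.0),
        (1.5, "mol/m^3", 1500.0),
        (1.85e-4, "mol/m^2/s", 1.85e-10),
        (5e10, "1/(M*s)", 5e4),
        (0.56e-6, "M", 0.56),
        (75.0, "cm/s", 7.5e5),
    ])
    def test_examples(self, value, unit, expected):
        assert ccmrd.convert_units(value, unit) == pytest.approx(expected,
                                                                 rel=1e-12)

    @pytest.mark.parametrize("unit", ["cm/s", "m/s", "mol/m^3", "mM",
                                      "mol/m^2/s", "nm", "1/(M*s)"])
    def test_round_trip(self, unit):
        x = 3.7216
        canonical = ccmrd.convert_units(x, unit)
        _, canon_unit = ccmrd.params._UNIT_TABLE[unit.replace(" ", "")]
        back = ccmrd.convert_units(canonical, canon_unit, to_unit=unit)
        assert back == pytest.approx(x, rel=1e-14)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            ccmrd.convert_units(1.0, "furlong/fortnight")
        with pytest.raises(ValueError, match="incompatible"):
            ccmrd.convert_units(1.0, "cm/s", to_unit="uM")

    def test_ppm_conversion_linear_and_zero(self):
        assert ccmrd.ppm_to_micromolar(0.0) == 0.0
        a = ccmrd.ppm_to_micromolar(100.0)
        assert ccmrd.ppm_to_micromolar(300.0) == pytest.approx(3 * a)

    def test_dissolved_round_trip(self):
        c = ccmrd.dissolved_from_ppm(412.0, 0.83)
        assert ccmrd.ppm_from_dissolved(c, 0.83) == pytest.approx(412.0)


class TestTable1Registry:
    def test_every_row_maps_to_exactly_one_field(self):
        fields = {f.name for f in dataclasses.fields(ParameterSet)}
        for row in TABLE1:
            assert row["field"] in fields, row["name"]

    def test_canonical_values_match_defaults(self):
        p = ParameterSet()
        for row in TABLE1:
            assert getattr(p, row["field"]) == pytest.approx(
                row["canonical"], rel=1e-12), row["name"]

    def test_printed_units_convert_to_canonical(self):
        for row in TABLE1:
            if row.get("raw") or row.get("rate"):
                continue
            got = ccmrd.convert_units(row["value"], row["unit"])
            assert got == pytest.approx(row["canonical"], rel=1e-12), row["name"]

    def test_oxygenation_vmax_derived_value(self):
        # the tabulated 1596 µM/s is Vmax_carb × kcat ratio
        assert ParameterSet().Vmax_oxy == pytest.approx(1596.0, rel=1e-12)


class TestBaselineModels:
    def test_land_plant_geometry(self):
        m = ccmrd.load_baseline("land_plant/no_pccm")
        assert m.compartment("stroma").r_outer == 4.63
        assert m.compartment("cytosol").r_outer == 8.77
        assert m.compartment("apoplast").r_outer == 10.0  # extended shell
        assert m.compartment("substomatal").r_outer == 11.63
        assert m.rubisco_compartment.name == "stroma"

    def test_alga_pccm_geometry(self):
        m = ccmrd.load_baseline("alga/pccm")
        assert m.compartment("pyrenoid").r_outer == 1.0
        assert m.compartment("stroma").pH == 8.0
        assert m.lumen is not None and m.lumen.pH == 6.0
        assert m.rubisco_compartment.name == "pyrenoid"
        assert m.lumen.endcap_area == pytest.approx(6 * math.pi * 0.25)

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="unknown model_id"):
            ccmrd.load_baseline("yeast/pccm")

    @pytest.mark.parametrize("model_id", ccmrd.MODEL_IDS)
    def test_all_baselines_validate(self, model_id):
        ccmrd.load_baseline(model_id).validate()

    def test_pccm_parts_only_in_pccm_models(self):
        for mid in ccmrd.MODEL_IDS:
            m = ccmrd.load_baseline(mid)
            names = {c.name for c in m.compartments}
            assert ("pyrenoid" in names) == m.has_pccm
            assert (m.lumen is not None) == m.has_pccm
            assert sum(c.rubisco for c in m.compartments) == 1

    def test_radii_ordering_enforced(self):
        with pytest.raises(ValueError, match="radii"):
            ParameterSet().replace(r_chloroplast=9.0)

    def test_invariant_bounds(self):
        with pytest.raises(ValueError):
            ParameterSet().replace(eff_porosity=1.5)
        with pytest.raises(ValueError):
            ParameterSet().replace(pH_stroma=15.0)
        with pytest.raises(ValueError):
            ParameterSet().replace(Vmax_carb=-1.0)

    def test_alga_boundary_is_equilibrated_dic(self, baseline_params):
        m = ccmrd.load_baseline("alga/no_pccm")
        p = baseline_params
        dic = equilibrium_dic(m.boundary.CO2_aq_uM, p.pH_external_water, p)
        assert m.boundary.HCO3_aq_uM == pytest.approx(dic["HCO3"])
        # the equilibrated pool is a fixed point of the spontaneous kinetics
        hyd, deprot = ccmrd.kinetics.spontaneous_interconversion(
            dic["CO2"], dic["H2CO3"], dic["HCO3"],
            hplus_micromolar(p.pH_external_water),
            p.k_hyd, p.k_dehyd, p.k_prot, p.k_deprot)
        assert hyd == pytest.approx(0.0, abs=1e-9)
        assert deprot == pytest.approx(0.0, abs=1e-9)


class TestPerturbations:
    def test_single_parameter_scaling(self, baseline_params):
        p = perturb_parameters(baseline_params, "Vmax_carb", 0.10)
        assert p.Vmax_carb == pytest.approx(8360.0)
        assert p.Km_CO2_rub == baseline_params.Km_CO2_rub

    def test_radius_one_percent(self, baseline_params):
        p = perturb_parameters(baseline_params, "r_cytosol", 0.01)
        assert p.r_cytosol == pytest.approx(8.8577)

    def test_porosity_down(self, baseline_params):
        p = perturb_parameters(baseline_params, "eff_porosity", -0.10)
        assert p.eff_porosity == pytest.approx(0.18)

    def test_inverse_recovers_baseline(self, baseline_params):
        p = perturb_parameters(baseline_params, "P_CO2", 0.10)
        back = perturb_parameters(p, "P_CO2", 1.0 / 1.1 - 1.0)
        assert back.P_CO2 == pytest.approx(baseline_params.P_CO2, rel=1e-12)

    def test_invariant_violation_raises(self, baseline_params):
        with pytest.raises(ValueError):
            perturb_parameters(baseline_params, "eff_porosity", 5.0)
        with pytest.raises(ValueError, match="unknown parameter"):
            perturb_parameters(baseline_params, "warp_factor", 0.1)

    def test_ensemble_deterministic_and_valid(self, baseline_params):
        a = perturb_ensemble(baseline_params, ["P_CO2", "Vmax_carb"], 5,
                             seed=11)
        b = perturb_ensemble(baseline_params, ["P_CO2", "Vmax_carb"], 5,
                             seed=11)
        assert len(a) == 5
        assert all(x.P_CO2 == y.P_CO2 for x, y in zip(a, b))
        for member in a:
            member.validate()


class TestScenarioGrid:
    def test_empty_axes_returns_base(self):
        base = ccmrd.load_baseline("land_plant/no_pccm")
        assert scenario_grid(base, {}) == [base]

    def test_cartesian_product_with_coords(self):
        base = ccmrd.build_model("land_plant/no_pccm",
                                 bica_location="chloroplast_envelope")
        grid = scenario_grid(base, {"p_co2_fold": [0.1, 1.0, 10.0],
                                    "bica_vmax": [0.0, 1e-10]})
        assert len(grid) == 6
        coords = [m.scenario["coords"] for m in grid]
        assert coords[0] == {"p_co2_fold": 0.1, "bica_vmax": 0.0}
        assert coords[-1] == {"p_co2_fold": 10.0, "bica_vmax": 1e-10}
        assert all(m.scenario["bica_location"] == "chloroplast_envelope"
                   for m in grid)

    def test_parameter_axis(self):
        grid = scenario_grid("land_plant/no_pccm",
                             {"eff_porosity": [1.0, 0.1, 0.01]})
        assert [m.params.eff_porosity for m in grid] == [1.0, 0.1, 0.01]

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty axis"):
            scenario_grid("land_plant/no_pccm", {"eff_porosity": []})
        with pytest.raises(ValueError, match="unknown axis"):
            scenario_grid("land_plant/no_pccm", {"no_such_param": [1]})


class TestYamlRoundTrip:
    def test_round_trip(self, baseline_params):
        text = ccmrd.parameters_to_yaml(baseline_params)
        back = ccmrd.parameters_from_yaml(text)
        assert back == baseline_params

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameters"):
            ccmrd.parameters_from_yaml("bogus_parameter: 3\n")
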