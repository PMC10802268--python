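"""Analysis drivers: compensation points, curves, sweeps, sensitivity."""

import math

import numpy as np
import pytest

import ccmrd
from ccmrd.experiments import (aci_curve, bica_sweep, compensation_point,
                               marginal_cost_crossover, marginal_cost_ratio,
                               model_variant, porosity_scan, run,
                               sensitivity_table)


@pytest.fixture(scope="module")
def comp_points():
    """Compensation points of all four baseline models (ppm)."""
    brackets = {"no_pccm": (20.0, 150.0), "pccm": (0.2, 30.0)}
    out = {}
    for mid in ccmrd.MODEL_IDS:
        out[mid] = compensation_point(
            mid, bracket_ppm=brackets[mid.split("/")[1]])
    return out


class TestCompensationPoint:
    def test_ccm_models_compensate_far_lower(self, comp_points):
        assert comp_points["land_plant/pccm"] < \
            0.5 * comp_points["land_plant/no_pccm"]
        assert comp_points["alga/pccm"] < 0.5 * comp_points["alga/no_pccm"]

    def test_deterministic(self, comp_points):
        again = compensation_point("alga/pccm", bracket_ppm=(0.2, 30.0))
        assert again == comp_points["alga/pccm"]

    def test_bracket_without_sign_change_rejected(self):
        with pytest.raises(ValueError, match="does not change sign"):
            compensation_point("land_plant/no_pccm",
                               bracket_ppm=(200.0, 400.0))


class TestAciCurve:
    def test_monotone_and_consistent_with_root(self, comp_points):
        cp = comp_points["land_plant/no_pccm"]
        levels = [20.0, 40.0, cp, 80.0, 150.0, 412.0]
        curve = aci_curve("land_plant/no_pccm", sorted(levels))
        assert curve.converged.all()
        assert np.all(np.diff(curve.net_fixation) > 0)  # monotone in CO2
        # exactly one sign change, at the compensation point
        signs = np.sign(curve.net_fixation)
        assert (np.diff(signs) != 0).sum() == 1
        at_root = curve.loc[curve.external_CO2_ppm == cp, "net_fixation"]
        assert abs(float(at_root.iloc[0])) < 1e-12 or \
            abs(float(at_root.iloc[0])) < 1e-3 * curve.net_fixation.abs().max()

    def test_near_zero_co2_is_carbon_negative(self):
        curve = aci_curve("alga/no_pccm", [1.0])
        assert float(curve.net_fixation.iloc[0]) < 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            aci_curve("alga/no_pccm", [-5.0, 10.0])
        with pytest.raises(ValueError):
            aci_curve("alga/no_pccm", [10.0, 5.0])


class TestBicaSweep:
    def test_zero_vmax_column_bitwise_matches_base_run(self):
        vmax = ccmrd.baseline_parameters().BicA_Vmax
        sweep = bica_sweep("land_plant", "chloroplast_envelope",
                           [1.0], [0.0, vmax])
        _, base = run(ccmrd.load_baseline("land_plant/no_pccm"))
        row = sweep.df[sweep.df.bica_vmax == 0.0].iloc[0]
        assert row.phi_CEF == base.phi_CEF              # bitwise
        assert row.rubisco_saturation == base.rubisco_saturation
        assert row.net_fixation == base.net_fixation

    def test_every_grid_point_recorded(self):
        sweep = bica_sweep("alga", "plasmalemma", [0.5, 1.0], [0.0, 1e-10])
        assert len(sweep.df) == 4
        assert sweep.df.converged.all()
        assert sweep.meta["pump_location"] == "plasmalemma"


class TestMarginalCostRatio:
    def test_identical_models_undefined(self, solved):
        _, s = solved("alga/no_pccm")
        assert math.isnan(marginal_cost_ratio(s, s))

    def test_nonfixing_reference_undefined(self, solved):
        _, s_p = solved("alga/pccm")
        curve = aci_curve("alga/no_pccm", [10.0])
        assert curve.net_fixation.iloc[0] < 0  # below compensation
        # build a summary with negative net fixation
        model = ccmrd.load_baseline("alga/no_pccm")
        from ccmrd.experiments import _with_external_ppm
        _, s_n = run(_with_external_ppm(model, 10.0))
        assert math.isnan(marginal_cost_ratio(s_p, s_n))

    def test_crossovers_bound_the_efficient_region(self):
        """The PCCM pays off (in photons) only below each crossover."""
        land = marginal_cost_crossover("land_plant", bracket=(120.0, 412.0))
        assert 100.0 < land < 412.0
        alga = marginal_cost_crossover("alga", bracket=(3.0, 13.8), tol=0.05)
        assert 2.0 < alga < 13.8  # well below air-equilibrated 13.8 µM


class TestPorosityScan:
    def test_invalid_porosity_rejected(self):
        with pytest.raises(ValueError):
            porosity_scan([0.0])
        with pytest.raises(ValueError):
            porosity_scan([1.5])

    def test_all_points_present_and_tagged(self):
        res = porosity_scan([0.2, 0.01], external_CO2_levels=(412.0,),
                            nodes_per_compartment=6)
        assert len(res.df) == 4
        assert set(res.df.model_id) == {"land_plant/pccm",
                                        "land_plant/no_pccm"}


class TestSensitivity:
    def test_inert_parameter_has_zero_response(self):
        table = sensitivity_table("land_plant/no_pccm",
                                  parameters=["BicA_Km_HCO3"],
                                  nodes_per_compartment=6)
        rows = table[table.parameter == "BicA_Km_HCO3"]
        assert (rows.d_saturation_pct == 0.0).all()
        assert (rows.d_phi_pct == 0.0).all()

    def test_rubisco_vmax_is_influential(self):
        table = sensitivity_table("land_plant/no_pccm",
                                  parameters=["Vmax_carb", "P_CO2"],
                                  nodes_per_compartment=6)
        vmax_rows = table[table.parameter == "Vmax_carb"]
        assert (vmax_rows.d_phi_pct > 0.1).all()
        assert vmax_rows.converged.all()

    def test_baseline_row_present_and_cytosol_radius_scaled(self):
        table = sensitivity_table("alga/no_pccm", parameters=["r_cytosol"],
                                  nodes_per_compartment=6)
        assert (table.parameter == "baseline").any()
        rows = table[table.parameter == "r_cytosol"]
        assert (rows.scale == 10.0).all()
        assert np.allclose(rows.perturbation.abs(), 0.01)

    def test_symmetric_perturbations_near_linear(self):
        table = sensitivity_table("alga/no_pccm", parameters=["D_CO2_w"],
                                  nodes_per_compartment=6)
        rows = table[table.parameter == "D_CO2_w"]
        up, down = rows.d_phi_pct.values
        assert up == pytest.approx(down, rel=0.5)


class TestModelVariant:
    def test_preserves_scenario(self):
        base = ccmrd.build_model("land_plant/no_pccm",
                                 bica_location="plasmalemma",
                                 apoplastic_ca=True)
        v = model_variant(base, p_co2_fold=2.0)
        assert v.scenario["bica_location"] == "plasmalemma"
        assert v.scenario["apoplastic_ca"] is True
        assert v.scenario["p_co2_fold"] == 2.0
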