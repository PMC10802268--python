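"""Steady-state solver: closed-form oracles, conservation, convergence."""

import numpy as np
import pytest

import ccmrd
from ccmrd.geometry import BoundaryEdge, Edge, RadialMesh, build_mesh
from ccmrd.params import SPECIES
from ccmrd.solver import (SteadyStateProblem, assemble_problem, solve_model,
                          solve_steady_state, stomatal_flux)


def toy_mesh(n, edges_co2, boundary_co2, volumes=None):
    """Hand-built transport network; the CO2 edge set is replicated for
    every species so the pure-transport problem is non-singular."""
    model = ccmrd.load_baseline("alga/no_pccm")
    volumes = np.ones(n) if volumes is None else np.asarray(volumes, float)
    edges = [Edge(e.a, e.b, s, e.G, e.alpha_a, e.alpha_b, e.tag)
             for e in edges_co2 for s in SPECIES]
    bedges = [BoundaryEdge(e.node, s, e.G, e.c_ext_eff, e.tag)
              for e in boundary_co2 for s in SPECIES]
    r = np.arange(n, dtype=float)
    return RadialMesh(
        model=model, r_lo=r, r_hi=r + 1, r_center=r + 0.5, volume=volumes,
        comp_name=["toy"] * n, is_aqueous=np.ones(n, bool),
        Hplus=np.zeros(n), ca_conc=np.zeros(n), lumen_ca_conc=np.zeros(n),
        lumen_ca_Hplus=np.zeros(n), rubisco_vmax=np.zeros(n),
        edges=edges, boundary_edges=bedges)


class TestTransportOracles:
    def test_uniform_concentration_closed_system_zero_residual(self):
        mesh = toy_mesh(4, [Edge(i, i + 1, "CO2", 2.5) for i in range(3)], [])
        prob = SteadyStateProblem(mesh, include_reactions=False)
        c = np.full(prob.n, 7.3)
        assert np.allclose(prob.residual(c), 0.0, atol=1e-12)

    def test_pure_transport_columns_conserve_mass(self):
        mesh = toy_mesh(4, [Edge(i, i + 1, "CO2", 1.7) for i in range(3)], [])
        prob = SteadyStateProblem(mesh, include_reactions=False)
        assert np.allclose(prob.A.sum(axis=0), 0.0, atol=1e-12)

    def test_linear_profile_between_fixed_ends(self):
        """1D chain with Dirichlet ends: the resistor-network oracle."""
        n, G = 5, 2.0
        cL, cR = 10.0, 2.0
        mesh = toy_mesh(
            n, [Edge(i, i + 1, "CO2", G) for i in range(n - 1)],
            [BoundaryEdge(0, "CO2", G, cL), BoundaryEdge(n - 1, "CO2", G, cR)])
        prob = SteadyStateProblem(mesh, include_reactions=False)
        sol = solve_steady_state(prob, initial_guess=np.full(prob.n, 5.0))
        assert sol.converged and sol.iterations <= 2  # linear: one step
        # independent oracle: equal resistances => arithmetic progression
        F = (cL - cR) / (n + 1) * G
        expected = [cL - F / G * (i + 1) for i in range(n)]
        co2 = [sol.c[prob.index[(i, "CO2")]] for i in range(n)]
        assert np.allclose(co2, expected, rtol=1e-10)

    def test_membrane_plus_sink_series_resistance_oracle(self):
        """Three nodes, one membrane, first-order sink at the core.

        Closed form: c0 = c_ext / (1 + k·V·ΣR) with the four resistances
        (boundary, diffusion, membrane, none) summed from outside in.
        """
        g_b, g_d, g_m = 5.0, 3.0, 0.8
        kV = 0.6  # first-order sink emulated as an edge to a zero reservoir
        c_ext = 20.0
        mesh = toy_mesh(
            3,
            [Edge(0, 1, "CO2", g_m), Edge(1, 2, "CO2", g_d)],
            [BoundaryEdge(2, "CO2", g_b, c_ext),
             BoundaryEdge(0, "CO2", kV, 0.0)])
        prob = SteadyStateProblem(mesh, include_reactions=False)
        sol = solve_steady_state(prob, initial_guess=np.ones(prob.n))
        assert sol.converged
        sum_R = 1 / g_b + 1 / g_d + 1 / g_m
        c0_expected = c_ext / (1.0 + kV * sum_R)
        assert sol.c[prob.index[(0, "CO2")]] == pytest.approx(c0_expected,
                                                              rel=1e-10)


class TestFullModels:
    @pytest.mark.parametrize("model_id", ccmrd.MODEL_IDS)
    def test_converges_with_balanced_flux_audit(self, model_id, solved):
        sol, _ = solved(model_id)
        assert sol.converged
        assert np.all(sol.c >= 0.0)
        assert sol.carbon_balance_error < 1e-3
        assert sol.oxygen_balance_error < 1e-3

    def test_solution_unique_across_initial_guesses(self):
        prob = assemble_problem(ccmrd.load_baseline("land_plant/pccm"))
        s1 = solve_steady_state(prob)
        s2 = solve_steady_state(prob, initial_guess=prob.initial_guess() * 3)
        s3 = solve_steady_state(prob, initial_guess=np.full(prob.n, 50.0))
        assert s2.converged and s3.converged
        for other in (s2, s3):
            rel = np.max(np.abs(other.c - s1.c) / (np.abs(s1.c) + 1e-12))
            assert rel < 1e-6

    @pytest.mark.parametrize("model_id", ["land_plant/pccm", "alga/pccm"])
    def test_ccm_concentrates_co2_in_pyrenoid(self, model_id, solved):
        sol, _ = solved(model_id)
        pyr = sol.concentration("pyrenoid", "CO2")
        stroma = sol.concentration("stroma", "CO2")
        cyt = sol.concentration("cytosol", "CO2")
        assert pyr > 5 * stroma
        assert pyr > 5 * cyt
        # the alkaline stroma stores carbon as bicarbonate: total DIC in
        # the stroma exceeds the cytosol's even where free CO2 does not
        dic = lambda comp: sum(sol.concentration(comp, s)
                               for s in ("CO2", "H2CO3", "HCO3"))
        assert dic("stroma") > dic("cytosol")

    @pytest.mark.parametrize("model_id", ["land_plant/no_pccm", "alga/pccm"])
    def test_mesh_doubling_stability(self, model_id):
        """Saturation and quantum yield move <2% when nodes double."""
        model = ccmrd.load_baseline(model_id)
        vals = {}
        for nodes in (12, 24):
            s = ccmrd.summarize(solve_model(model, nodes_per_compartment=nodes))
            vals[nodes] = (s.rubisco_saturation, s.phi_CEF)
        for a, b in zip(vals[12], vals[24]):
            assert abs(b - a) / abs(a) < 0.02

    def test_lumen_ca_flux_only_in_pccm_models(self, solved):
        sol_p, _ = solved("alga/pccm")
        sol_n, _ = solved("alga/no_pccm")
        assert sol_p.fluxes["J_CA_lumen"] > 0
        assert sol_n.fluxes["J_CA_lumen"] == 0.0

    def test_solution_table_dump(self, solved):
        sol, _ = solved("land_plant/no_pccm")
        table = sol.to_table()
        assert {"r_um", "compartment", "species", "conc_uM"} <= set(table.columns)
        assert (table.conc_uM >= 0).all()

    def test_wrong_guess_length_rejected(self):
        prob = assemble_problem(ccmrd.load_baseline("alga/no_pccm"))
        with pytest.raises(ValueError):
            solve_steady_state(prob, initial_guess=np.ones(3))


class TestStomatalBoundary:
    def test_no_gradient_no_flux(self):
        assert stomatal_flux(412.0, 412.0, 0.4375, 100.0) == 0.0

    def test_scalar_value(self):
        # g_s·V_m = 10845.6 µm/s equivalent permeability
        f = stomatal_flux(412.0, 411.0, 0.4375, 1.0)
        assert f == pytest.approx(0.4375 * 24.79e3 * (1.0 / 24.79), rel=1e-12)

    def test_clamp_mode_fixes_substomatal_co2(self):
        model = ccmrd.build_model("land_plant/no_pccm",
                                  clamp_substomatal_ppm=243.0)
        sol = solve_model(model)
        assert sol.converged
        # gas node removed from the unknowns; wall flux still audited
        assert all(sol.mesh.is_aqueous[i]
                   for i, _ in sol.problem.node_species)
        assert sol.fluxes["boundary_carbon_in"] == pytest.approx(
            sol.fluxes["Vc"], rel=1e-3)

    def test_doubling_gs_halves_stomatal_drawdown(self):
        draws = []
        for factor in (1.0, 2.0):
            p = ccmrd.baseline_parameters()
            p = p.replace(g_s=p.g_s * factor)
            model = ccmrd.build_model("land_plant/no_pccm", params=p)
            sol = solve_model(model)
            sub_ppm = sol.concentration("substomatal", "CO2") * p.molar_volume_air
            draws.append(412.0 - sub_ppm)
        assert draws[0] / draws[1] == pytest.approx(2.0, rel=0.05)
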