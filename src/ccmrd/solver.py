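"""Steady-state solution of the reaction-diffusion network.

The discrete problem is a finite-volume balance: for every node and
species, diffusive exchange with radial neighbours + membrane/boundary
fluxes + reaction sources = 0.  Linear terms (diffusion, permeation,
spontaneous DIC interconversion at fixed compartment pH, Dirichlet
boundaries) are assembled once into a matrix; the nonlinear sources
(rubisco, carbonic anhydrase, BicA pumps) contribute local residual and
Jacobian blocks.  The steady state is found by damped Newton iteration
with positivity safeguarding, with pseudo-transient continuation as a
fallback, and every solution carries a whole-cell flux audit (carbon and
oxygen balances close at steady state).

Internal flux unit: µM·µm³·s⁻¹ ≡ 10⁻²¹ mol·s⁻¹ (= 10⁻¹⁵ µmol·s⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .geometry import RadialMesh, build_mesh
from .params import SPECIES, CellModel, dissolved_from_ppm, ppm_to_micromolar

__all__ = ["SteadyStateProblem", "SteadyStateSolution", "assemble_problem",
           "solve_steady_state", "solve_model", "stomatal_flux",
           "FLUX_UNIT_TO_UMOL"]

#: µM·µm³/s expressed in µmol/s
FLUX_UNIT_TO_UMOL = 1.0e-15


def stomatal_flux(C_atm_ppm: float, C_sub_ppm: float, g_s: float,
                  area_um2: float, molar_volume_air: float = 24.79) -> float:
    """Gas flux (µM·µm³/s) from the atmosphere into the substomatal space.

    g_s (mol m⁻² s⁻¹ per unit mole fraction) acts on the mixing-ratio
    difference over the stomatal exchange area.
    """
    if g_s < 0:
        raise ValueError("stomatal conductance must be non-negative")
    P = g_s * molar_volume_air * 1e3  # equivalent gas permeability, µm/s
    dC = (ppm_to_micromolar(C_atm_ppm, molar_volume_air)
          - ppm_to_micromolar(C_sub_ppm, molar_volume_air))
    return P * area_um2 * dC


class SteadyStateProblem:
    """Residual/Jacobian assembly for one mesh.

    ``include_reactions=False`` yields the pure transport network (used by
    closed-form oracle tests).
    """

    def __init__(self, mesh: RadialMesh, include_reactions: bool = True):
        self.mesh = mesh
        self.model = mesh.model
        p = self.model.params
        self.include_reactions = include_reactions

        clamped_gas = (self.model.boundary.kind == "atmosphere"
                       and self.model.boundary.clamp_substomatal_ppm is not None)
        self.index: dict[tuple[int, str], int] = {}
        self.node_species: list[tuple[int, str]] = []
        for i in range(mesh.n_nodes):
            if mesh.is_aqueous[i]:
                species = SPECIES
            elif clamped_gas:
                species = ()
            else:
                species = ("CO2",)
            for s in species:
                self.index[(i, s)] = len(self.node_species)
                self.node_species.append((i, s))
        self.n = len(self.node_species)

        A = np.zeros((self.n, self.n))
        b = np.zeros(self.n)

        for e in mesh.edges:
            ia = self.index[(e.a, e.species)]
            ib = self.index[(e.b, e.species)]
            A[ia, ia] -= e.G * e.alpha_a
            A[ia, ib] += e.G * e.alpha_b
            A[ib, ia] += e.G * e.alpha_a
            A[ib, ib] -= e.G * e.alpha_b
        for e in mesh.boundary_edges:
            i = self.index[(e.node, e.species)]
            A[i, i] -= e.G
            b[i] += e.G * e.c_ext_eff

        if include_reactions:
            # spontaneous DIC interconversion, linear at fixed pH
            for i in range(mesh.n_nodes):
                if not mesh.is_aqueous[i]:
                    continue
                V = mesh.volume[i]
                H = mesh.Hplus[i]
                ico2 = self.index[(i, "CO2")]
                ih2 = self.index[(i, "H2CO3")]
                ihco3 = self.index[(i, "HCO3")]
                # hydration net: k_hyd*CO2 - k_dehyd*H2CO3
                A[ico2, ico2] -= V * p.k_hyd
                A[ico2, ih2] += V * p.k_dehyd
                A[ih2, ico2] += V * p.k_hyd
                A[ih2, ih2] -= V * p.k_dehyd
                # deprotonation net: k_deprot*H2CO3 - k_prot*H*HCO3
                A[ih2, ih2] -= V * p.k_deprot
                A[ih2, ihco3] += V * p.k_prot * H
                A[ihco3, ih2] += V * p.k_deprot
                A[ihco3, ihco3] -= V * p.k_prot * H

        self.A = A
        self.b = b
        self._absA = np.abs(A)

        # nonlinear bookkeeping
        self.rubisco_entries: list[tuple[int, int, float, int]] = []
        self.ca_entries: list[tuple[int, int, float, float, float, bool, int]] = []
        self.pump_entries: list[tuple[int, int, float, float, str]] = []
        if include_reactions:
            for i in range(mesh.n_nodes):
                if not mesh.is_aqueous[i]:
                    continue
                V = mesh.volume[i]
                if mesh.rubisco_vmax[i] > 0:
                    self.rubisco_entries.append(
                        (self.index[(i, "CO2")], self.index[(i, "O2")],
                         mesh.rubisco_vmax[i], i))
                if mesh.ca_conc[i] > 0:
                    self.ca_entries.append(
                        (self.index[(i, "CO2")], self.index[(i, "HCO3")],
                         mesh.ca_conc[i], mesh.Hplus[i], V, False, i))
                if mesh.lumen_ca_conc[i] > 0:
                    self.ca_entries.append(
                        (self.index[(i, "CO2")], self.index[(i, "HCO3")],
                         mesh.lumen_ca_conc[i], mesh.lumen_ca_Hplus[i], V,
                         True, i))
            for t in mesh.transporter_edges:
                self.pump_entries.append(
                    (self.index[(t.src, t.species)],
                     self.index[(t.dst, t.species)],
                     t.vmax_total, t.km, t.name))

        self.volumes = np.array([mesh.volume[i] for i, _ in self.node_species])

    # -- nonlinear pieces ---------------------------------------------------

    def _rubisco_terms(self, c, R=None, J=None):
        p = self.model.params
        Kc, Ko = p.Km_CO2_rub, p.Km_O2_rub
        for ico2, io2, vmax, node in self.rubisco_entries:
            V = self.mesh.volume[node]
            CO2, O2 = c[ico2], c[io2]
            den_c = CO2 + Kc * (1.0 + O2 / Ko)
            den_o = O2 + Ko * (1.0 + CO2 / Kc)
            Vc = vmax * CO2 / den_c
            Vo = vmax * p.kcat_ratio * O2 / den_o
            if R is not None:
                R[ico2] -= V * Vc
                R[io2] -= V * Vo
            if J is not None:
                J[ico2, ico2] -= V * vmax * Kc * (1 + O2 / Ko) / den_c ** 2
                J[ico2, io2] -= V * (-vmax * CO2 * Kc / Ko / den_c ** 2)
                J[io2, io2] -= V * (vmax * p.kcat_ratio * Ko *
                                    (1 + CO2 / Kc) / den_o ** 2)
                J[io2, ico2] -= V * (-vmax * p.kcat_ratio * O2 * Ko / Kc
                                     / den_o ** 2)

    def _ca_terms(self, c, R=None, J=None):
        p = self.model.params
        for ico2, ihco3, conc, H, V, _is_lumen, _node in self.ca_entries:
            CO2, HCO3 = c[ico2], c[ihco3]
            num = conc * p.CA_kcat * (CO2 - HCO3 * H / p.CA_Keq)
            den = p.CA_Km_CO2 + HCO3 * p.CA_Km_CO2 / p.CA_Km_HCO3 + CO2
            rate = num / den  # µM/s, positive = hydration
            if R is not None:
                R[ico2] -= V * rate
                R[ihco3] += V * rate
            if J is not None:
                dr_dco2 = conc * p.CA_kcat / den - rate / den
                dr_dhco3 = (-conc * p.CA_kcat * H / p.CA_Keq / den
                            - rate * (p.CA_Km_CO2 / p.CA_Km_HCO3) / den)
                J[ico2, ico2] -= V * dr_dco2
                J[ico2, ihco3] -= V * dr_dhco3
                J[ihco3, ico2] += V * dr_dco2
                J[ihco3, ihco3] += V * dr_dhco3

    def _pump_terms(self, c, R=None, J=None):
        for isrc, idst, vmax, km, _name in self.pump_entries:
            S = c[isrc]
            F = vmax * S / (km + S)
            if R is not None:
                R[isrc] -= F
                R[idst] += F
            if J is not None:
                dF = vmax * km / (km + S) ** 2
                J[isrc, isrc] -= dF
                J[idst, isrc] += dF

    # -- public assembly ------------------------------------------------------

    def residual(self, c: np.ndarray) -> np.ndarray:
        """Net production (µM·µm³/s) per unknown; zero at steady state."""
        R = self.A @ c + self.b
        self._rubisco_terms(c, R=R)
        self._ca_terms(c, R=R)
        self._pump_terms(c, R=R)
        return R

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        J = self.A.copy()
        self._rubisco_terms(c, J=J)
        self._ca_terms(c, J=J)
        self._pump_terms(c, J=J)
        return J

    def flux_scale(self, c: np.ndarray) -> float:
        """Characteristic gross flux magnitude used for the relative
        convergence criterion."""
        gross = self._absA @ np.abs(c) + np.abs(self.b)
        return max(float(gross.max()), 1e-12)

    def initial_guess(self) -> np.ndarray:
        """Boundary-equilibrated concentrations per compartment."""
        p = self.model.params
        bc = self.model.boundary
        if bc.kind == "atmosphere":
            ppm = (bc.clamp_substomatal_ppm
                   if bc.clamp_substomatal_ppm is not None else bc.CO2_ppm)
            co2_aq = dissolved_from_ppm(ppm, p.H_CO2, p.molar_volume_air)
            o2_aq = dissolved_from_ppm(bc.O2_frac * 1e6, p.H_O2,
                                       p.molar_volume_air)
            co2_gas = ppm_to_micromolar(ppm, p.molar_volume_air)
        else:
            co2_aq = bc.CO2_aq_uM
            o2_aq = bc.O2_aq_uM
            co2_gas = co2_aq / p.H_CO2
        c = np.empty(self.n)
        for k, (i, s) in enumerate(self.node_species):
            if not self.mesh.is_aqueous[i]:
                c[k] = co2_gas
                continue
            H = self.mesh.Hplus[i]
            if s == "CO2":
                c[k] = co2_aq
            elif s == "H2CO3":
                c[k] = co2_aq * p.k_hyd / p.k_dehyd
            elif s == "HCO3":
                c[k] = co2_aq * (p.k_hyd / p.k_dehyd) * p.k_deprot / (
                    p.k_prot * H)
            else:
                c[k] = o2_aq
        return np.maximum(c, 1e-9)


def assemble_problem(model: CellModel, mesh: RadialMesh | None = None,
                     nodes_per_compartment: int = 12) -> SteadyStateProblem:
    """Build the discrete steady-state problem for a CellModel."""
    if mesh is None:
        mesh = build_mesh(model, nodes_per_compartment)
    return SteadyStateProblem(mesh)


@dataclass
class SteadyStateSolution:
    """Converged concentration fields plus a whole-cell flux audit.

    Fluxes are in µM·µm³·s⁻¹ (multiply by 1e-15 for µmol/s).  The audit
    verifies that at steady state the boundary carbon uptake equals the
    integrated carboxylation flux and the boundary O2 uptake equals the
    integrated oxygenation flux (the model's only sinks).
    """
    model: CellModel
    mesh: RadialMesh
    c: np.ndarray
    problem: SteadyStateProblem
    converged: bool
    iterations: int
    residual_norm: float
    fluxes: dict[str, float] = field(default_factory=dict)

    def concentration(self, compartment: str, species: str) -> float:
        """Volume-weighted mean concentration (µM) in a compartment."""
        nodes = self.mesh.nodes_of(compartment)
        idx = [self.problem.index.get((int(i), species)) for i in nodes]
        keep = [(k, int(i)) for k, i in zip(idx, nodes) if k is not None]
        if not keep:
            raise KeyError(f"{species} not tracked in {compartment}")
        vals = np.array([self.c[k] for k, _ in keep])
        vols = np.array([self.mesh.volume[i] for _, i in keep])
        return float(np.sum(vals * vols) / np.sum(vols))

    def profile(self, species: str) -> pd.DataFrame:
        rows = []
        for k, (i, s) in enumerate(self.problem.node_species):
            if s != species:
                continue
            rows.append({"node": i, "r_um": self.mesh.r_center[i],
                         "compartment": self.mesh.comp_name[i],
                         "conc_uM": self.c[k]})
        return pd.DataFrame(rows)

    def to_table(self) -> pd.DataFrame:
        """Tidy dump: node radius, compartment, species, concentration."""
        rows = []
        for k, (i, s) in enumerate(self.problem.node_species):
            rows.append({"node": i, "r_um": self.mesh.r_center[i],
                         "compartment": self.mesh.comp_name[i],
                         "species": s, "conc_uM": self.c[k]})
        return pd.DataFrame(rows)

    @property
    def carbon_balance_error(self) -> float:
        vc = self.fluxes["Vc"]
        if vc == 0:
            return 0.0
        return abs(self.fluxes["boundary_carbon_in"] - vc) / abs(vc)

    @property
    def oxygen_balance_error(self) -> float:
        vo = self.fluxes["Vo"]
        if vo == 0:
            return 0.0
        return abs(self.fluxes["boundary_O2_in"] - vo) / abs(vo)


def _audit(problem: SteadyStateProblem, c: np.ndarray) -> dict[str, float]:
    mesh = problem.mesh
    p = problem.model.params
    fl: dict[str, float] = {}

    Vc = Vo = 0.0
    Kc, Ko = p.Km_CO2_rub, p.Km_O2_rub
    for ico2, io2, vmax, node in problem.rubisco_entries:
        V = mesh.volume[node]
        CO2, O2 = c[ico2], c[io2]
        Vc += V * vmax * CO2 / (CO2 + Kc * (1 + O2 / Ko))
        Vo += V * vmax * p.kcat_ratio * O2 / (O2 + Ko * (1 + CO2 / Kc))
    fl["Vc"] = Vc
    fl["Vo"] = Vo

    j_lumen = 0.0
    for ico2, ihco3, conc, H, V, is_lumen, _node in problem.ca_entries:
        num = conc * p.CA_kcat * (c[ico2] - c[ihco3] * H / p.CA_Keq)
        den = p.CA_Km_CO2 + c[ihco3] * p.CA_Km_CO2 / p.CA_Km_HCO3 + c[ico2]
        rate = num / den
        if is_lumen:
            j_lumen += V * (-rate)  # positive = net dehydration
    fl["J_CA_lumen"] = j_lumen

    for isrc, idst, vmax, km, name in problem.pump_entries:
        fl[f"pump_{name}"] = vmax * c[isrc] / (km + c[isrc])

    carbon_in = o2_in = 0.0
    stomatal = 0.0
    for e in mesh.boundary_edges:
        i = problem.index.get((e.node, e.species))
        flux = e.G * (e.c_ext_eff - (c[i] if i is not None else 0.0))
        if e.tag.startswith("stomata"):
            stomatal += flux
        elif e.species == "O2":
            o2_in += flux
        else:
            carbon_in += flux
    for e in mesh.edges:
        if e.tag.startswith("wall_air"):
            ia = problem.index[(e.a, e.species)]
            ib = problem.index[(e.b, e.species)]
            flux = e.G * (e.alpha_a * c[ia] - e.alpha_b * c[ib])
            if e.species == "CO2":
                carbon_in += flux
            else:
                o2_in += flux
    fl["boundary_carbon_in"] = carbon_in
    fl["boundary_O2_in"] = o2_in
    fl["stomatal_CO2_in"] = stomatal if stomatal else carbon_in
    return fl


def solve_steady_state(problem: SteadyStateProblem,
                       initial_guess: np.ndarray | None = None,
                       tol: float = 1e-11, max_iter: int = 200,
                       ) -> SteadyStateSolution:
    """Damped Newton with positivity safeguarding; pseudo-transient
    continuation fallback.  Converged when the residual ∞-norm falls below
    ``tol`` × the characteristic gross flux scale.  Deterministic for
    fixed inputs."""
    c = problem.initial_guess() if initial_guess is None else \
        np.maximum(np.asarray(initial_guess, dtype=float).copy(), 1e-12)
    if c.shape != (problem.n,):
        raise ValueError("initial guess has wrong length")

    c, converged, iters, rnorm = _newton(problem, c, tol, max_iter)
    if not converged:
        c, converged, extra, rnorm = _pseudo_transient(problem, c, tol,
                                                       max_iter=400)
        iters += extra

    sol = SteadyStateSolution(
        model=problem.model, mesh=problem.mesh, c=c, problem=problem,
        converged=converged, iterations=iters, residual_norm=rnorm,
        fluxes=_audit(problem, c))
    return sol


def _newton(problem, c, tol, max_iter):
    R = problem.residual(c)
    rnorm = float(np.abs(R).max())
    for it in range(max_iter):
        scale = problem.flux_scale(c)
        if rnorm <= tol * scale:
            return c, True, it, rnorm
        J = problem.jacobian(c)
        try:
            dc = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            return c, False, it, rnorm
        # positivity safeguard: never step more than 99.9% toward zero
        neg = dc < 0
        if np.any(neg):
            alpha_max = float(np.min(0.999 * c[neg] / (-dc[neg])))
            alpha = min(1.0, alpha_max)
        else:
            alpha = 1.0
        improved = False
        for _ in range(40):
            c_try = c + alpha * dc
            R_try = problem.residual(c_try)
            r_try = float(np.abs(R_try).max())
            if r_try < rnorm * (1.0 - 1e-4 * alpha) or r_try <= tol * scale:
                c, R, rnorm = c_try, R_try, r_try
                improved = True
                break
            alpha *= 0.5
        if not improved:
            return c, False, it + 1, rnorm
    scale = problem.flux_scale(c)
    return c, rnorm <= tol * scale, max_iter, rnorm


def _pseudo_transient(problem, c, tol, max_iter):
    """Implicit-Euler march toward steady state with growing step."""
    M = problem.volumes.copy()
    dt = 1e-6
    R = problem.residual(c)
    rnorm = float(np.abs(R).max())
    for it in range(max_iter):
        scale = problem.flux_scale(c)
        if rnorm <= tol * scale:
            return c, True, it, rnorm
        J = problem.jacobian(c) - np.diag(M / dt)
        try:
            dc = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            dt *= 0.25
            continue
        neg = dc < 0
        alpha = 1.0
        if np.any(neg):
            alpha = min(1.0, float(np.min(0.999 * c[neg] / (-dc[neg]))))
        c_try = np.maximum(c + alpha * dc, 1e-15)
        R_try = problem.residual(c_try)
        r_try = float(np.abs(R_try).max())
        if r_try <= rnorm * 1.5:
            c, R, rnorm = c_try, R_try, r_try
            dt = min(dt * 2.0, 1e6)
        else:
            dt *= 0.25
            if dt < 1e-12:
                return c, False, it, rnorm
    scale = problem.flux_scale(c)
    return c, rnorm <= tol * scale, max_iter, rnorm


def solve_model(model: CellModel, nodes_per_compartment: int = 12,
                initial_guess: np.ndarray | None = None,
                tol: float = 1e-11, max_iter: int = 200,
                ) -> SteadyStateSolution:
    """Convenience: mesh + assemble + solve in one call."""
    problem = assemble_problem(model,
                               nodes_per_compartment=nodes_per_compartment)
    return solve_steady_state(problem, initial_guess=initial_guess, tol=tol,
                              max_iter=max_iter)
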