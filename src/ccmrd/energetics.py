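"""Energetics of steady-state carbon assimilation.

Converts the flux audit of a steady state into net fixation, ATP/NADPH
demand, photon demand and quantum yield:

* net fixation = Vc − Vo/2 (half a CO2 is lost downstream per
  oxygenation);
* ATP demand = 3·Vc + 3.5·Vo plus the indirect cost of thylakoid-lumen
  carbonic anhydrase activity, J_CA,lumen · 3/14 (each HCO3− dehydrated in
  the acidic lumen consumes one pumped proton of pmf, and the ATP synthase
  makes one ATP per 14/3 protons);
* NADPH demand = 2·(Vc + Vo);
* photons: linear electron flow delivers Photons_base photons, 2 NADPH
  and ATP_base ATP per unit.  Any ATP deficit relative to the demanded
  ATP:NADPH ratio is made up either by cyclic electron flow (a fixed
  photon cost per deficit ATP) or by the malate valve (export of excess
  NADPH at 5.45 ATP per 2 NADPH, 4 photons per NADPH);
* quantum yield φ = net fixation / total photons.

All extensive quantities are reported in µmol·s⁻¹ per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet
from .solver import FLUX_UNIT_TO_UMOL, SteadyStateSolution

__all__ = ["EnergeticsSummary", "net_fixation", "lumen_ca_atp_cost",
           "photon_demand", "rubisco_saturation", "summarize"]


def net_fixation(Vc: float, Vo: float) -> float:
    """Net CO2 fixation Vc − Vo/2 (same units as the inputs)."""
    if Vc < 0 or Vo < 0:
        raise ValueError("fluxes must be non-negative")
    return Vc - 0.5 * Vo


def lumen_ca_atp_cost(J_CA_lumen: float, H_per_ATP: float = 14.0 / 3.0) -> float:
    """Indirect ATP cost of lumenal CA dehydration flux: J · 3/14."""
    if J_CA_lumen < 0:
        raise ValueError("lumen CA flux must be non-negative")
    return J_CA_lumen / H_per_ATP


def photon_demand(Vc: float, Vo: float, ATP_demand: float,
                  NADPH_demand: float, mode: str,
                  p: ParameterSet) -> tuple[float, float, float]:
    """Total photon demand and quantum yield under a rebalancing mode.

    Returns ``(photons_total, phi, photons_per_reaction)``.  The demanded
    ATP:NADPH ratio fixes the ATP deficit per linear-electron-flow unit
    (which makes NADPH_base NADPH and ATP_base ATP from Photons_base
    photons); the deficit is priced in photons via cyclic electron flow
    (``mode="CEF"``) or the malate valve (``mode="malate"``).  An ATP
    surplus needs no extra photons (the deficit is floored at zero).
    """
    if mode == "CEF":
        k_extra = p.k_CEF_photons_per_ATP
    elif mode == "malate":
        k_extra = (p.NADPH_base / p.malate_ATP_per_2NADPH) * p.photons_per_NADPH
    else:
        raise ValueError(f"unknown rebalancing mode {mode!r}")
    total_rxn = Vc + Vo
    if total_rxn <= 0 or NADPH_demand <= 0:
        return 0.0, 0.0, 0.0
    ratio = ATP_demand / NADPH_demand
    deficit = max(ratio * p.NADPH_base - p.ATP_base, 0.0)
    per_rxn = p.Photons_base + deficit * k_extra
    photons_total = total_rxn * per_rxn
    phi = net_fixation(Vc, Vo) / photons_total
    return photons_total, phi, per_rxn


def rubisco_saturation(Vc: float, Vmax_capacity: float) -> float:
    """Achieved carboxylation as % of the total catalytic capacity."""
    if Vmax_capacity <= 0:
        raise ValueError("capacity must be positive")
    return 100.0 * Vc / Vmax_capacity


@dataclass(frozen=True)
class EnergeticsSummary:
    """Whole-cell energetics of one steady state (extensive, µmol/s)."""
    Vc: float
    Vo: float
    net_fixation: float
    ATP_demand: float
    NADPH_demand: float
    ATP_cost_lumen_CA: float
    ATP_cost_BicA: float
    ratio: float                 # ATP/NADPH demanded
    photons_total_CEF: float
    photons_total_malate: float
    phi_CEF: float               # net CO2 per photon
    phi_malate: float
    rubisco_saturation: float    # %
    converged: bool

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "Vc", "Vo", "net_fixation", "ATP_demand", "NADPH_demand",
            "ATP_cost_lumen_CA", "ATP_cost_BicA", "ratio", "photons_total_CEF",
            "photons_total_malate", "phi_CEF", "phi_malate",
            "rubisco_saturation", "converged")}

    def to_text(self) -> str:
        """Flat key-value structured-text serialization."""
        return "\n".join(f"{k}: {v}" for k, v in self.to_dict().items())


def summarize(solution: SteadyStateSolution) -> EnergeticsSummary:
    """EnergeticsSummary from a solved steady state."""
    p = solution.model.params
    u = FLUX_UNIT_TO_UMOL
    Vc = solution.fluxes["Vc"] * u
    Vo = solution.fluxes["Vo"] * u
    j_lumen = max(solution.fluxes.get("J_CA_lumen", 0.0), 0.0) * u
    atp_ca = lumen_ca_atp_cost(j_lumen, p.H_per_ATP)
    # active bicarbonate pumping is charged per transported HCO3−
    pump_total = sum(v for k, v in solution.fluxes.items()
                     if k.startswith("pump_")) * u
    atp_bica = p.ATP_per_bica * pump_total
    atp = p.ATP_per_carb * Vc + p.ATP_per_oxy * Vo + atp_ca + atp_bica
    nadph = p.NADPH_per_rxn * (Vc + Vo)
    ratio = atp / nadph if nadph > 0 else float("nan")
    ph_cef, phi_cef, _ = photon_demand(Vc, Vo, atp, nadph, "CEF", p)
    ph_mal, phi_mal, _ = photon_demand(Vc, Vo, atp, nadph, "malate", p)

    mesh = solution.mesh
    capacity = 0.0  # total catalytic capacity, µM·µm³/s -> µmol/s
    for i in range(mesh.n_nodes):
        if mesh.rubisco_vmax[i] > 0:
            capacity += mesh.rubisco_vmax[i] * mesh.volume[i]
    sat = rubisco_saturation(Vc, capacity * u)

    return EnergeticsSummary(
        Vc=Vc, Vo=Vo, net_fixation=net_fixation(Vc, Vo),
        ATP_demand=atp, NADPH_demand=nadph, ATP_cost_lumen_CA=atp_ca,
        ATP_cost_BicA=atp_bica,
        ratio=ratio, photons_total_CEF=ph_cef, photons_total_malate=ph_mal,
        phi_CEF=phi_cef, phi_malate=phi_mal, rubisco_saturation=sat,
        converged=solution.converged)
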