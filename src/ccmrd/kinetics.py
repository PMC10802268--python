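"""Pure rate laws for carbon-assimilation reaction-diffusion models.

Every function here is a stateless mapping from local concentrations and
kinetic parameters to a rate.  Unit contract:

* concentrations       µM
* volumetric rates     µM s⁻¹
* areal flux densities µM·µm s⁻¹  (multiply by an area in µm² to get
  µM·µm³ s⁻¹ ≡ 10⁻²¹ mol s⁻¹)
* permeabilities       µm s⁻¹
* diffusivities        µm² s⁻¹

Sign conventions are stated per function.  All rate laws return exactly
zero at their thermodynamic equilibrium or zero-substrate point and are
monotone in their driving substrate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rubisco_carboxylation",
    "rubisco_oxygenation",
    "vmax_oxygenation",
    "carbonic_anhydrase",
    "spontaneous_interconversion",
    "membrane_permeation",
    "bica_transport",
    "gas_dissolution_flux",
    "series_conductance",
]


def _check_nonneg(**concs: float) -> None:
    for name, value in concs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"negative concentration for {name}: {value}")


def rubisco_carboxylation(CO2, O2, Vmax_carb, Km_CO2_rub, Km_O2_rub):
    """Carboxylation rate Vc (µM/s) with O2 as a competitive inhibitor.

    Vc = Vmax_c * CO2 / (CO2 + Km_CO2 * (1 + O2/Km_O2))
    """
    _check_nonneg(CO2=CO2, O2=O2)
    return Vmax_carb * CO2 / (CO2 + Km_CO2_rub * (1.0 + O2 / Km_O2_rub))


def vmax_oxygenation(Vmax_carb, kcat_ratio):
    """Oxygenation Vmax from the carboxylation Vmax and the kcat ratio."""
    if Vmax_carb <= 0 or kcat_ratio <= 0:
        raise ValueError("Vmax_carb and kcat_ratio must be positive")
    return Vmax_carb * kcat_ratio


def rubisco_oxygenation(CO2, O2, Vmax_oxy, Km_CO2_rub, Km_O2_rub):
    """Oxygenation rate Vo (µM/s); the competitive mirror image of Vc.

    Vo = Vmax_o * O2 / (O2 + Km_O2 * (1 + CO2/Km_CO2))
    """
    _check_nonneg(CO2=CO2, O2=O2)
    return Vmax_oxy * O2 / (O2 + Km_O2_rub * (1.0 + CO2 / Km_CO2_rub))


def carbonic_anhydrase(CO2, HCO3, Hplus, CA_conc, kcat, Km_CO2, Km_HCO3, Keq):
    """Net reversible CA rate (µM/s); positive = hydration (CO2 -> HCO3−).

    rate = CA·kcat·(CO2 − HCO3·H⁺/Keq)
           / (Km_CO2 + HCO3·Km_CO2/Km_HCO3 + CO2)

    H⁺ (µM) is fixed by the compartment pH.  The rate vanishes exactly at
    the equilibrium CO2 = HCO3·H⁺/Keq; the sign is the net direction, so a
    negative value is net dehydration (HCO3− -> CO2), the dominant
    direction in an acidic thylakoid lumen.
    """
    _check_nonneg(CO2=CO2, HCO3=HCO3, Hplus=Hplus)
    num = CA_conc * kcat * (CO2 - HCO3 * Hplus / Keq)
    den = Km_CO2 + HCO3 * Km_CO2 / Km_HCO3 + CO2
    return num / den


def spontaneous_interconversion(CO2, H2CO3, HCO3, Hplus,
                                k_hyd, k_dehyd, k_prot, k_deprot):
    """Uncatalysed DIC interconversion; returns two net rates (µM/s).

    hydration net      = k_hyd·CO2 − k_dehyd·H2CO3      (CO2 -> H2CO3)
    deprotonation net  = k_deprot·H2CO3 − k_prot·HCO3·H⁺ (H2CO3 -> HCO3−)

    k_prot is in µM⁻¹ s⁻¹ and H⁺ in µM (fixed by compartment pH).  Both
    nets vanish simultaneously at detailed balance.
    """
    _check_nonneg(CO2=CO2, H2CO3=H2CO3, HCO3=HCO3, Hplus=Hplus)
    hyd = k_hyd * CO2 - k_dehyd * H2CO3
    deprot = k_deprot * H2CO3 - k_prot * HCO3 * Hplus
    return hyd, deprot


def membrane_permeation(P, outside, inside):
    """Passive lipid-membrane flux density P·(outside − inside).

    Positive = inward.  Antisymmetric under swapping the two sides.
    """
    if np.any(np.asarray(P) < 0):
        raise ValueError("permeability must be non-negative")
    return P * (outside - inside)


def bica_transport(HCO3_source, BicA_Vmax, BicA_Km):
    """Unidirectional saturable bicarbonate-pump flux density.

    Michaelis-Menten in the source-side HCO3−: Vmax·S/(Km + S).
    Vmax is an areal rate (µM·µm s⁻¹ after unit conversion).
    """
    _check_nonneg(HCO3_source=HCO3_source)
    return BicA_Vmax * HCO3_source / (BicA_Km + HCO3_source)


def gas_dissolution_flux(C_air, C_water, D_w, H, delta_w):
    """Gas dissolution through an unstirred water film (µM·µm/s, positive
    into the water).

    flux = (D_w/δ_w) · (H·C_air − C_water)

    ``H`` is the dimensionless aqueous:gas partition coefficient (Henry
    solubility ratio, e.g. ≈0.83 for CO2 at 25 °C), so the flux vanishes
    when the water is at Henry equilibrium C_water = H·C_air.
    """
    _check_nonneg(C_air=C_air, C_water=C_water)
    if delta_w <= 0:
        raise ValueError("water-layer thickness must be positive")
    return (D_w / delta_w) * (H * C_air - C_water)


def series_conductance(*conductances):
    """Combine conductances (µm³/s) in series: invert, sum, invert.

    Zero anywhere gives zero overall (a blocked path); used for the
    water-film + cell-wall gas entry path of the land-plant models.
    """
    g = np.asarray(conductances, dtype=float)
    if np.any(g < 0):
        raise ValueError("conductances must be non-negative")
    if np.any(g == 0):
        return 0.0
    return 1.0 / np.sum(1.0 / g)
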