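"""Parameter registry and cell-model construction.

Single source of truth for every model parameter, in canonical internal
units (µm, s, µM, µmol·µm⁻²·s⁻¹), plus builders for the four baseline
models — a C3 land-plant mesophyll cell and a green-algal cell, each with
and without a pyrenoid-based carbon-concentrating mechanism (PCCM) — and
their scenario variants (BicA pumps at the chloroplast envelope or
plasmalemma, apoplastic carbonic anhydrase, apoplast pH overrides,
membrane-permeability folds, cell-wall porosity series, external-CO2
scaling).

The registry doubles as the package's synthetic-scenario generator:
`perturb_parameters` produces one-at-a-time perturbed parameter sets (and
seeded log-uniform ensembles), and `scenario_grid` expands Cartesian
sweeps, so every downstream stage is testable without external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "Compartment",
    "Membrane",
    "Transporter",
    "LumenSpec",
    "Boundary",
    "CellModel",
    "MODEL_IDS",
    "TABLE1",
    "baseline_parameters",
    "load_baseline",
    "build_model",
    "convert_units",
    "ppm_to_micromolar",
    "dissolved_from_ppm",
    "ppm_from_dissolved",
    "hplus_micromolar",
    "equilibrium_dic",
    "perturb_parameters",
    "perturb_ensemble",
    "scenario_grid",
    "parameters_to_yaml",
    "parameters_from_yaml",
]

MODEL_IDS = (
    "land_plant/no_pccm",
    "land_plant/pccm",
    "alga/no_pccm",
    "alga/pccm",
)

# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

#: recognised unit -> (multiplicative factor, canonical unit)
_UNIT_TABLE: dict[str, tuple[float, str]] = {
    # velocities / permeabilities -> µm/s
    "um/s": (1.0, "um/s"),
    "mm/s": (1e3, "um/s"),
    "cm/s": (1e4, "um/s"),
    "m/s": (1e6, "um/s"),
    # diffusivities -> µm²/s
    "um^2/s": (1.0, "um^2/s"),
    "cm^2/s": (1e8, "um^2/s"),
    "m^2/s": (1e12, "um^2/s"),
    # concentrations -> µM
    "uM": (1.0, "uM"),
    "mM": (1e3, "uM"),
    "M": (1e6, "uM"),
    "mol/m^3": (1e3, "uM"),  # 1 mol/m³ = 1 mM
    "umol/L": (1.0, "uM"),
    # lengths -> µm
    "um": (1.0, "um"),
    "nm": (1e-3, "um"),
    "mm": (1e3, "um"),
    "m": (1e6, "um"),
    # areal rates -> µmol/µm²/s
    "umol/um^2/s": (1.0, "umol/um^2/s"),
    "mol/m^2/s": (1e-6, "umol/um^2/s"),  # 1 mol/m² = 1e6 µmol / 1e12 µm²
    # first/second-order rate constants
    "1/s": (1.0, "1/s"),
    "1/(M*s)": (1e-6, "1/(uM*s)"),
    "1/(uM*s)": (1.0, "1/(uM*s)"),
}


def convert_units(value: float, from_unit: str, to_unit: str | None = None) -> float:
    """Convert ``value`` from ``from_unit`` to canonical internal units.

    Canonical units are µm/s, µm²/s, µM, µm, µmol·µm⁻²·s⁻¹, 1/s and
    1/(µM·s) depending on the dimension of ``from_unit``.  Passing
    ``to_unit`` converts between any two recognised units of the same
    dimension (so the conversion round-trips exactly).
    """
    key = from_unit.replace(" ", "")
    if key not in _UNIT_TABLE:
        raise ValueError(f"unrecognized unit: {from_unit!r}")
    factor, canonical = _UNIT_TABLE[key]
    canonical_value = value * factor
    if to_unit is None:
        return canonical_value
    tkey = to_unit.replace(" ", "")
    if tkey not in _UNIT_TABLE:
        raise ValueError(f"unrecognized unit: {to_unit!r}")
    tfactor, tcanonical = _UNIT_TABLE[tkey]
    if tcanonical != canonical:
        raise ValueError(f"incompatible units: {from_unit!r} -> {to_unit!r}")
    return canonical_value / tfactor


def ppm_to_micromolar(ppm: float, molar_volume_air: float = 24.79) -> float:
    """Gas-phase mixing ratio (ppm) to gas-phase concentration (µM).

    412 ppm at 24.79 L/mol gives ≈16.62 µmol CO2 per litre of air; a
    partial-pressure fraction is converted by passing fraction·1e6.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    if molar_volume_air <= 0:
        raise ValueError("molar volume must be positive")
    return ppm / molar_volume_air


def dissolved_from_ppm(ppm: float, H: float, molar_volume_air: float = 24.79) -> float:
    """Aqueous concentration (µM) at Henry equilibrium with a gas at ``ppm``."""
    return ppm_to_micromolar(ppm, molar_volume_air) * H


def ppm_from_dissolved(c_aq: float, H: float, molar_volume_air: float = 24.79) -> float:
    """Gas-phase ppm in Henry equilibrium with a dissolved concentration (µM)."""
    if H <= 0:
        raise ValueError("Henry partition coefficient must be positive")
    return c_aq / H * molar_volume_air


def hplus_micromolar(pH: float) -> float:
    """Proton concentration (µM) for a pH."""
    return 10.0 ** (-pH) * 1e6


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

SPECIES = ("CO2", "H2CO3", "HCO3", "O2")


@dataclass(frozen=True)
class ParameterSet:
    """Every model parameter in canonical internal units.

    Units: lengths µm, times s, concentrations µM, diffusivities µm²/s,
    permeabilities µm/s, areal transporter Vmax µmol·µm⁻²·s⁻¹.
    """

    # diffusion coefficients in water, µm²/s
    D_CO2_w: float = 1.88e3
    D_H2CO3_w: float = 1.2e3
    D_HCO3_w: float = 1.15e3
    D_O2_w: float = 2.42e3

    # lipid-membrane permeabilities, µm/s
    P_CO2: float = 3.5e3          # 3.5e-3 m/s, the Gutknecht value
    P_CO2_high: float = 3.2e4     # 3.2e-2 m/s, upper literature estimate
    P_H2CO3: float = 30.0
    P_HCO3: float = 0.05
    P_O2: float = 7.5e5           # 75 cm/s; effectively non-limiting

    # channel-mediated permeabilities, µm/s
    P_BLP_HCO3: float = 1.0e4     # bestrophin-like channels, thylakoid
    P_LCIA_HCO3: float = 1.0e-2   # LCIA, chloroplast envelope

    starch_sheath_factor: float = 0.1  # multiplies P_CO2 (DIC) / P_O2 (O2)

    # spontaneous interconversion rate constants
    k_hyd: float = 6.0e-2         # 1/s
    k_dehyd: float = 20.0         # 1/s
    k_deprot: float = 1.0e7       # 1/s
    k_prot: float = 5.0e4         # 1/(µM·s)  (5e10 M⁻¹ s⁻¹)

    # carbonic anhydrase
    CA_kcat: float = 3.0e5        # 1/s
    CA_Km_CO2: float = 1.5e3      # µM
    CA_Km_HCO3: float = 3.4e4     # µM
    CA_Keq: float = 0.56          # µM (first DIC acid equilibrium constant)
    CA_conc_stroma: float = 270.0   # µM
    CA_conc_cytosol: float = 135.0  # µM
    CA_conc_lumen: float = 135.0    # µM
    CA_conc_apoplast: float = 135.0  # µM, used only when apoplastic CA is on

    # rubisco
    Vmax_carb: float = 7.6e3      # µM/s
    kcat_ratio: float = 0.21      # oxygenation/carboxylation kcat ratio
    Km_CO2_rub: float = 8.6       # µM (dissolved)
    Km_O2_rub: float = 215.0      # µM (dissolved)

    # BicA bicarbonate pump
    BicA_Vmax: float = 1.85e-10   # µmol·µm⁻²·s⁻¹ (1.85e-4 mol m⁻² s⁻¹)
    BicA_Km_HCO3: float = 217.0   # µM

    # external conditions
    g_s: float = 0.4375           # stomatal conductance, mol m⁻² s⁻¹
    ext_CO2_ppm: float = 412.0
    ext_O2_frac: float = 0.2095   # O2 partial-pressure fraction
    molar_volume_air: float = 24.79  # L/mol

    # Henry aqueous:gas partition coefficients (dimensionless, 25 °C)
    H_CO2: float = 0.83
    H_O2: float = 0.032

    # wall / unstirred layers, µm
    delta_wall: float = 0.32
    delta_wall_bryophyte: float = 1.6
    delta_water: float = 0.32     # apoplast water film (land plant)
    delta_bl: float = 0.32        # unstirred boundary layer (alga)
    eff_porosity: float = 0.2     # C3 angiosperm cell wall
    eff_porosity_hornwort: float = 1.0e-4
    airspace_fraction: float = 0.5

    # geometry, µm
    r_pyrenoid: float = 1.0
    r_tubule: float = 0.5
    tubule_length: float = 4.0
    n_tubules: int = 6
    r_chloroplast: float = 4.63
    r_cytosol: float = 8.77
    r_plasmalemma_surface: float = 9.23   # as tabulated; see apoplast_outer
    apoplast_outer_radius: float = 10.0   # extended apoplast water layer
    r_substomatal: float = 11.63

    # compartment pH
    pH_apoplast: float = 6.0
    pH_external_water: float = 8.1
    pH_cytosol: float = 7.2
    pH_stroma: float = 8.0
    pH_lumen: float = 6.0

    # energetic stoichiometries
    ATP_per_carb: float = 3.0
    ATP_per_oxy: float = 3.5
    ATP_per_bica: float = 1.0     # ATP per HCO3− actively pumped
    NADPH_per_rxn: float = 2.0
    H_per_ATP: float = 14.0 / 3.0
    Photons_base: float = 8.0
    NADPH_base: float = 2.0
    ATP_base: float = 12.0 * 3.0 / 14.0   # ≈2.571 ATP per LEF unit
    k_CEF_photons_per_ATP: float = 0.43
    malate_ATP_per_2NADPH: float = 5.45
    photons_per_NADPH: float = 4.0

    # ---- derived quantities -------------------------------------------------

    @property
    def Vmax_oxy(self) -> float:
        """Oxygenation Vmax (µM/s), Vmax_carb × kcat ratio."""
        return self.Vmax_carb * self.kcat_ratio

    @property
    def P_stomatal(self) -> float:
        """Stomatal conductance as an equivalent gas permeability (µm/s).

        g_s (mol m⁻² s⁻¹ per unit mole fraction) × molar volume of air
        converts a mixing-ratio driving force into a gas-concentration one:
        0.4375 × 24.79 L/mol = 10845.6 µm/s.
        """
        return self.g_s * self.molar_volume_air * 1.0e3

    @property
    def atm_CO2_gas_uM(self) -> float:
        return ppm_to_micromolar(self.ext_CO2_ppm, self.molar_volume_air)

    @property
    def atm_O2_gas_uM(self) -> float:
        return ppm_to_micromolar(self.ext_O2_frac * 1e6, self.molar_volume_air)

    def diffusivity(self, species: str) -> float:
        return {"CO2": self.D_CO2_w, "H2CO3": self.D_H2CO3_w,
                "HCO3": self.D_HCO3_w, "O2": self.D_O2_w}[species]

    def membrane_permeability(self, species: str, p_co2_fold: float = 1.0) -> float:
        return {"CO2": self.P_CO2 * p_co2_fold, "H2CO3": self.P_H2CO3,
                "HCO3": self.P_HCO3, "O2": self.P_O2}[species]

    # ---- validation ---------------------------------------------------------

    def validate(self) -> None:
        positive = [
            "D_CO2_w", "D_H2CO3_w", "D_HCO3_w", "D_O2_w",
            "P_CO2", "P_CO2_high", "P_H2CO3", "P_HCO3", "P_O2",
            "P_BLP_HCO3", "P_LCIA_HCO3", "starch_sheath_factor",
            "k_hyd", "k_dehyd", "k_deprot", "k_prot",
            "CA_kcat", "CA_Km_CO2", "CA_Km_HCO3", "CA_Keq",
            "Vmax_carb", "kcat_ratio", "Km_CO2_rub", "Km_O2_rub",
            "BicA_Km_HCO3", "g_s", "molar_volume_air", "H_CO2", "H_O2",
            "delta_wall", "delta_water", "delta_bl",
            "r_pyrenoid", "r_tubule", "tubule_length",
            "r_chloroplast", "r_cytosol", "apoplast_outer_radius",
            "r_substomatal",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        nonneg = ["CA_conc_stroma", "CA_conc_cytosol", "CA_conc_lumen",
                  "CA_conc_apoplast", "BicA_Vmax", "ext_CO2_ppm", "ext_O2_frac"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.eff_porosity <= 1.0):
            raise ValueError("eff_porosity must lie in (0, 1]")
        if not (0.0 < self.airspace_fraction <= 1.0):
            raise ValueError("airspace_fraction must lie in (0, 1]")
        for name in ["pH_apoplast", "pH_external_water", "pH_cytosol",
                     "pH_stroma", "pH_lumen"]:
            if not (0.0 <= getattr(self, name) <= 14.0):
                raise ValueError(f"{name} must lie in [0, 14]")
        if not (self.r_pyrenoid < self.r_chloroplast < self.r_cytosol
                < self.apoplast_outer_radius < self.r_substomatal):
            raise ValueError("radii must increase from innermost to outermost")

    def replace(self, **changes: Any) -> "ParameterSet":
        new = dataclasses.replace(self, **changes)
        new.validate()
        return new

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def baseline_parameters() -> ParameterSet:
    """The baseline parameter set (validated)."""
    p = ParameterSet()
    p.validate()
    return p


# ---------------------------------------------------------------------------
# machine-readable copy of the published baseline-parameter table
# ---------------------------------------------------------------------------

#: rows: (name, printed value(s), printed unit, ParameterSet field, canonical
#: value, note).  A field may consume more than one row (scanned ranges); every
#: row maps to exactly one field.  Two reconciliations against the sources are
#: applied and noted: the rubisco Km rows are transposed as printed (the cited
#: tobacco kinetics give Kc ≈ 8.6 µM and Ko ≈ 215 µM dissolved, the only
#: assignment consistent with the reported compensation points), and the CA
#: equilibrium constant is read in molar units (0.56 µM), which agrees with
#: the spontaneous rate constants (0.6 µM) where the printed mol/m³ reading
#: is off by three orders of magnitude.
TABLE1: list[dict[str, Any]] = [
    dict(name="Diffusion coefficient of CO2 in water", value=1.88e3,
         unit="um^2/s", field="D_CO2_w", canonical=1.88e3),
    dict(name="Diffusion coefficient of H2CO3 in water", value=1.2e3,
         unit="um^2/s", field="D_H2CO3_w", canonical=1.2e3),
    dict(name="Diffusion coefficient of HCO3- in water", value=1.15e3,
         unit="um^2/s", field="D_HCO3_w", canonical=1.15e3),
    dict(name="Diffusion coefficient of O2 in water", value=2.42e3,
         unit="um^2/s", field="D_O2_w", canonical=2.42e3),
    dict(name="Membrane permeability to CO2 (lower reported value)",
         value=3.5e-3, unit="m/s", field="P_CO2", canonical=3.5e3),
    dict(name="Membrane permeability to CO2 (upper reported value)",
         value=3.2e-2, unit="m/s", field="P_CO2_high", canonical=3.2e4),
    dict(name="Membrane permeability to H2CO3", value=30.0, unit="um/s",
         field="P_H2CO3", canonical=30.0),
    dict(name="Membrane permeability to HCO3-", value=0.05, unit="um/s",
         field="P_HCO3", canonical=0.05),
    dict(name="Membrane permeability to O2", value=75.0, unit="cm/s",
         field="P_O2", canonical=7.5e5),
    dict(name="Bestrophin-like channel mediated permeability of thylakoid "
              "to HCO3-", value=1.0e-2, unit="m/s", field="P_BLP_HCO3",
         canonical=1.0e4),
    dict(name="Chloroplast membrane permeability to HCO3- mediated by LCIA",
         value=1.0e-8, unit="m/s", field="P_LCIA_HCO3", canonical=1.0e-2),
    dict(name="Rate constant of spontaneous hydration of CO2", value=6.0e-2,
         unit="1/s", field="k_hyd", canonical=6.0e-2),
    dict(name="Rate constant of spontaneous dehydration of H2CO3", value=20.0,
         unit="1/s", field="k_dehyd", canonical=20.0),
    dict(name="Rate constant of spontaneous deprotonation of H2CO3",
         value=1.0e7, unit="1/s", field="k_deprot", canonical=1.0e7),
    dict(name="Rate constant of spontaneous protonation of HCO3-",
         value=5.0e10, unit="1/(M*s)", field="k_prot", canonical=5.0e4),
    dict(name="Carbonic anhydrase kcat", value=3.0e5, unit="1/s",
         field="CA_kcat", canonical=3.0e5),
    dict(name="Carbonic anhydrase Km for CO2", value=1.5, unit="mol/m^3",
         field="CA_Km_CO2", canonical=1.5e3),
    dict(name="Carbonic anhydrase Keq", value=0.56e-6, unit="M",
         field="CA_Keq", canonical=0.56,
         note="unit read as molar; consistent with the spontaneous rate "
              "constants (0.6 uM)"),
    dict(name="Carbonic anhydrase Km for HCO3", value=34.0, unit="mol/m^3",
         field="CA_Km_HCO3", canonical=3.4e4),
    dict(name="Carbonic anhydrase concentration in stroma", value=270.0,
         unit="uM", field="CA_conc_stroma", canonical=270.0),
    dict(name="Carbonic anhydrase concentration in cytosol", value=135.0,
         unit="uM", field="CA_conc_cytosol", canonical=135.0),
    dict(name="Carbonic anhydrase concentration in lumen", value=135.0,
         unit="uM", field="CA_conc_lumen", canonical=135.0),
    dict(name="Rubisco Vmax of carboxylation", value=7600.0, unit="umol/L",
         field="Vmax_carb", canonical=7.6e3, rate=True),
    dict(name="Rubisco Vmax of oxygenation", value=1596.0, unit="umol/L",
         field="kcat_ratio", canonical=0.21, rate=True,
         note="derived: Vmax_carb x kcat ratio 0.21 = 1596 uM/s"),
    dict(name="Rubisco Km O2", value=8.6, unit="umol/L",
         field="Km_CO2_rub", canonical=8.6,
         note="rows transposed as printed; 8.6 uM is the dissolved-CO2 Km "
              "of the cited tobacco kinetics"),
    dict(name="Rubisco Km CO2", value=215.0, unit="umol/L",
         field="Km_O2_rub", canonical=215.0,
         note="rows transposed as printed; 215 uM is the dissolved-O2 Km"),
    dict(name="BicA Vmax", value=1.85e-4, unit="mol/m^2/s",
         field="BicA_Vmax", canonical=1.85e-10),
    dict(name="BicA Km HCO3-", value=0.217, unit="mol/m^3",
         field="BicA_Km_HCO3", canonical=217.0),
    dict(name="Stomatal conductance", value=0.4375, unit="mol/m^2/s",
         field="g_s", canonical=0.4375, raw=True),
    dict(name="Atmospheric concentration of CO2", value=412.0, unit="ppm",
         field="ext_CO2_ppm", canonical=412.0, raw=True),
    dict(name="Atmospheric concentration of O2", value=0.2095,
         unit="partial pressure", field="ext_O2_frac", canonical=0.2095,
         raw=True),
    dict(name="Thickness of cell wall in angiosperms", value=0.32, unit="um",
         field="delta_wall", canonical=0.32),
    dict(name="Thickness of cell wall in bryophytes", value=1.6, unit="um",
         field="delta_wall_bryophyte", canonical=1.6),
    dict(name="Effective porosity of C3 plant cell wall", value=0.2,
         unit="unitless", field="eff_porosity", canonical=0.2, raw=True),
    dict(name="Effective porosity of hornwort cell wall", value=1.0e-4,
         unit="unitless", field="eff_porosity_hornwort", canonical=1.0e-4,
         raw=True),
    dict(name="Thickness of unstirred boundary layer in algal model",
         value=0.32, unit="um", field="delta_bl", canonical=0.32),
    dict(name="Thickness of unstirred apoplast water layer in land plant "
              "models", value=0.32, unit="um", field="delta_water",
         canonical=0.32),
    dict(name="Permeability of pyrenoid starch sheath to dissolved "
              "inorganic carbon", value=0.1, unit="unitless",
         field="starch_sheath_factor", canonical=0.1, raw=True,
         note="0.1 x P_CO2 for CO2, H2CO3 and HCO3-"),
    dict(name="Permeability of pyrenoid starch sheath to oxygen", value=0.1,
         unit="unitless", field="starch_sheath_factor", canonical=0.1,
         raw=True, note="0.1 x P_O2"),
    dict(name="Radius of pyrenoid", value=1.0, unit="um", field="r_pyrenoid",
         canonical=1.0),
    dict(name="Radius of thylakoid", value=0.5, unit="um", field="r_tubule",
         canonical=0.5),
    dict(name="Height of thylakoid", value=4.0, unit="um",
         field="tubule_length", canonical=4.0),
    dict(name="Radius of chloroplast", value=4.63, unit="um",
         field="r_chloroplast", canonical=4.63),
    dict(name="Radius of cytosol", value=8.77, unit="um", field="r_cytosol",
         canonical=8.77),
    dict(name="Radius of plasmalemma surface", value=9.23, unit="um",
         field="r_plasmalemma_surface", canonical=9.23,
         note="the apoplast water shell is extended to 10 um in the model"),
    dict(name="Radius of substomatal space in land plant model", value=11.63,
         unit="um", field="r_substomatal", canonical=11.63),
    dict(name="Proportion of cell wall adjacent to intercellular airspace "
              "in land plant", value=0.5, unit="unitless",
         field="airspace_fraction", canonical=0.5, raw=True),
    dict(name="pH of land plant apoplast", value=6.0, unit="pH",
         field="pH_apoplast", canonical=6.0, raw=True),
    dict(name="pH of ocean water", value=8.1, unit="pH",
         field="pH_external_water", canonical=8.1, raw=True),
    dict(name="pH of cytosol", value=7.2, unit="pH", field="pH_cytosol",
         canonical=7.2, raw=True),
    dict(name="pH of stroma", value=8.0, unit="pH", field="pH_stroma",
         canonical=8.0, raw=True),
    dict(name="pH of lumen", value=6.0, unit="pH", field="pH_lumen",
         canonical=6.0, raw=True),
]


# ---------------------------------------------------------------------------
# cell-model description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """One concentric shell (or the lumped thylakoid lumen).

    ``ca_conc`` is a carbonic anhydrase operating at the compartment pH;
    ``lumen_ca_conc``/``lumen_ca_pH`` describe the pyrenoid-hosted CA
    reaction that is evaluated at thylakoid-lumen pH (the PCCM's CO2
    release step).
    """
    name: str
    r_inner: float
    r_outer: float
    phase: str  # "aqueous" | "gas"
    pH: float | None = None
    ca_conc: float = 0.0
    rubisco: bool = False
    rubisco_vmax_factor: float = 1.0
    lumen_ca_conc: float = 0.0
    lumen_ca_pH: float | None = None


@dataclass(frozen=True)
class Transporter:
    """Unidirectional saturable pump at a membrane interface."""
    name: str
    species: str
    source: str          # "outer" | "inner": which side supplies substrate
    vmax_areal: float    # µmol·µm⁻²·s⁻¹
    km: float            # µM


@dataclass(frozen=True)
class Membrane:
    """Interface between two adjacent shells.

    ``kind`` is "lipid" (permeability law) or "gas_series" (the land-plant
    wall/air entry: water-film and cell-wall conductances in series with a
    Henry partition; only volatile species cross).
    """
    name: str
    inner: str
    outer: str
    kind: str = "lipid"
    permeabilities: Mapping[str, float] = field(default_factory=dict)
    transporters: tuple[Transporter, ...] = ()
    area_deduction: float = 0.0   # µm² removed (tubule end caps at sheath)


@dataclass(frozen=True)
class LumenSpec:
    """Lumped thylakoid-lumen compartment and its two couplings."""
    volume: float          # µm³
    pH: float
    lateral_area: float    # µm², to the stroma
    endcap_area: float     # µm², to the pyrenoid
    permeabilities_lateral: Mapping[str, float] = field(default_factory=dict)
    permeabilities_endcap: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Boundary:
    """External boundary condition.

    kind "atmosphere": fixed-ppm air beyond the stomata (land plant); the
    substomatal CO2 may instead be clamped directly.
    kind "bulk_water": Dirichlet DIC/O2 pools at the outside of the
    unstirred layer (alga), equilibrated at the stated pH.
    """
    kind: str
    CO2_ppm: float | None = None
    O2_frac: float | None = None
    clamp_substomatal_ppm: float | None = None
    CO2_aq_uM: float | None = None
    H2CO3_aq_uM: float | None = None
    HCO3_aq_uM: float | None = None
    O2_aq_uM: float | None = None
    pH: float | None = None


@dataclass(frozen=True)
class CellModel:
    """A fully specified model: shells, interfaces, boundary, scenario."""
    model_id: str
    organism: str
    has_pccm: bool
    params: ParameterSet
    compartments: tuple[Compartment, ...]
    membranes: tuple[Membrane, ...]
    lumen: LumenSpec | None
    boundary: Boundary
    scenario: Mapping[str, Any] = field(default_factory=dict)

    @property
    def rubisco_compartment(self) -> Compartment:
        (comp,) = [c for c in self.compartments if c.rubisco]
        return comp

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"model_id": self.model_id,
             "params": self.params.as_dict(),
             "scenario": dict(self.scenario),
             "boundary": dataclasses.asdict(self.boundary)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        self.params.validate()
        rub = [c for c in self.compartments if c.rubisco]
        if len(rub) != 1:
            raise ValueError("exactly one compartment must carry rubisco")
        names = {c.name for c in self.compartments}
        pccm_parts = {"pyrenoid"}
        if self.has_pccm:
            if not pccm_parts <= names or self.lumen is None:
                raise ValueError("PCCM model must contain pyrenoid and lumen")
            if rub[0].name != "pyrenoid":
                raise ValueError("PCCM rubisco belongs in the pyrenoid")
        else:
            if pccm_parts & names or self.lumen is not None:
                raise ValueError("non-PCCM model must not contain PCCM parts")
            if rub[0].name != "stroma":
                raise ValueError("non-PCCM rubisco belongs in the stroma")
        shells = [c for c in self.compartments]
        for a, b in zip(shells, shells[1:]):
            if not math.isclose(a.r_outer, b.r_inner):
                raise ValueError("compartment shells must be contiguous")
            if a.r_outer <= a.r_inner:
                raise ValueError("compartment shells must have positive width")
        if self.organism == "land_plant" and "substomatal" not in names:
            raise ValueError("land-plant model needs a substomatal gas space")
        if self.organism == "alga" and "boundary_layer" not in names:
            raise ValueError("algal model needs an unstirred boundary layer")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def equilibrium_dic(CO2_aq: float, pH: float, p: ParameterSet) -> dict[str, float]:
    """DIC speciation (µM) in equilibrium with a dissolved CO2 at a pH.

    Uses the spontaneous rate constants: H2CO3 = CO2·k_hyd/k_dehyd and
    HCO3− = H2CO3·k_deprot/(k_prot·H⁺).
    """
    h2co3 = CO2_aq * p.k_hyd / p.k_dehyd
    hco3 = h2co3 * p.k_deprot / (p.k_prot * hplus_micromolar(pH))
    return {"CO2": CO2_aq, "H2CO3": h2co3, "HCO3": hco3}


def _parse_model_id(model_id: str) -> tuple[str, bool]:
    canonical = model_id.replace("-", "/").replace(".", "/")
    if canonical not in MODEL_IDS:
        raise ValueError(
            f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    organism, pccm = canonical.split("/")
    return organism, pccm == "pccm"


def _lipid_perms(p: ParameterSet, p_co2_fold: float,
                 extra_hco3: float = 0.0) -> dict[str, float]:
    perms = {s: p.membrane_permeability(s, p_co2_fold) for s in SPECIES}
    perms["HCO3"] += extra_hco3
    return perms


def build_model(
    model_id: str,
    params: ParameterSet | None = None,
    *,
    p_co2_fold: float = 1.0,
    external_co2_scale: float = 1.0,
    bica_location: str | None = None,
    bica_vmax: float | None = None,
    bica_km: float | None = None,
    apoplastic_ca: bool = False,
    apoplast_pH: float | None = None,
    clamp_substomatal_ppm: float | None = None,
) -> CellModel:
    """Build one of the four base models or a scenario variant.

    Parameters
    ----------
    model_id
        "land_plant/no_pccm", "land_plant/pccm", "alga/no_pccm" or
        "alga/pccm".
    p_co2_fold
        Fold change of lipid-membrane CO2 permeability relative to the
        Gutknecht baseline; also scales the starch-sheath DIC permeability,
        which is defined as a fraction of P_CO2.
    external_co2_scale
        Scales the boundary CO2 (and for the alga the whole equilibrated
        DIC pool) relative to the 412-ppm baseline.
    bica_location
        None, "chloroplast_envelope" or "plasmalemma"; adds a
        unidirectional BicA pump with ``bica_vmax`` (defaults to the
        tabulated Vmax) and ``bica_km``.
    apoplastic_ca, apoplast_pH
        Land-plant scenario switches: carbonic anhydrase in the apoplast
        water and an apoplast pH override.
    clamp_substomatal_ppm
        Fix the substomatal gas CO2 instead of feeding it through the
        stomatal conductance (used for the marginal-cost analysis).
    """
    p = params if params is not None else baseline_parameters()
    p.validate()
    organism, has_pccm = _parse_model_id(model_id)
    model_id = f"{organism}/{'pccm' if has_pccm else 'no_pccm'}"

    if bica_location not in (None, "chloroplast_envelope", "plasmalemma"):
        raise ValueError(f"unknown bica_location {bica_location!r}")
    vmax_b = p.BicA_Vmax if bica_vmax is None else bica_vmax
    km_b = p.BicA_Km_HCO3 if bica_km is None else bica_km

    compartments: list[Compartment] = []
    membranes: list[Membrane] = []
    lumen: LumenSpec | None = None

    # --- chloroplast interior -------------------------------------------
    v_chloro = 4.0 / 3.0 * math.pi * p.r_chloroplast ** 3
    if has_pccm:
        v_pyr = 4.0 / 3.0 * math.pi * p.r_pyrenoid ** 3
        compartments.append(Compartment(
            name="pyrenoid", r_inner=0.0, r_outer=p.r_pyrenoid,
            phase="aqueous", pH=p.pH_stroma, ca_conc=0.0, rubisco=True,
            rubisco_vmax_factor=1.0,
            lumen_ca_conc=p.CA_conc_lumen, lumen_ca_pH=p.pH_lumen))
        compartments.append(Compartment(
            name="stroma", r_inner=p.r_pyrenoid, r_outer=p.r_chloroplast,
            phase="aqueous", pH=p.pH_stroma, ca_conc=p.CA_conc_stroma))
        sheath_dic = p.starch_sheath_factor * p.P_CO2 * p_co2_fold
        endcap_area = p.n_tubules * math.pi * p.r_tubule ** 2
        membranes.append(Membrane(
            name="starch_sheath", inner="pyrenoid", outer="stroma",
            permeabilities={"CO2": sheath_dic, "H2CO3": sheath_dic,
                            "HCO3": sheath_dic,
                            "O2": p.starch_sheath_factor * p.P_O2},
            area_deduction=endcap_area))
        lateral_area = p.n_tubules * 2.0 * math.pi * p.r_tubule * p.tubule_length
        lumen_volume = p.n_tubules * math.pi * p.r_tubule ** 2 * p.tubule_length
        thylakoid_perm = _lipid_perms(p, p_co2_fold, extra_hco3=p.P_BLP_HCO3)
        lumen = LumenSpec(
            volume=lumen_volume, pH=p.pH_lumen,
            lateral_area=lateral_area, endcap_area=endcap_area,
            permeabilities_lateral=thylakoid_perm,
            permeabilities_endcap=thylakoid_perm)
    else:
        compartments.append(Compartment(
            name="stroma", r_inner=0.0, r_outer=p.r_chloroplast,
            phase="aqueous", pH=p.pH_stroma, ca_conc=p.CA_conc_stroma,
            rubisco=True))

    # --- envelope and cytosol -------------------------------------------
    envelope_transporters: tuple[Transporter, ...] = ()
    if bica_location == "chloroplast_envelope":
        envelope_transporters = (Transporter(
            name="BicA", species="HCO3", source="outer",
            vmax_areal=vmax_b, km=km_b),)
    membranes.append(Membrane(
        name="chloroplast_envelope", inner="stroma", outer="cytosol",
        permeabilities=_lipid_perms(
            p, p_co2_fold, extra_hco3=p.P_LCIA_HCO3 if has_pccm else 0.0),
        transporters=envelope_transporters))
    compartments.append(Compartment(
        name="cytosol", r_inner=p.r_chloroplast, r_outer=p.r_cytosol,
        phase="aqueous", pH=p.pH_cytosol, ca_conc=p.CA_conc_cytosol))

    plasmalemma_transporters: tuple[Transporter, ...] = ()
    if bica_location == "plasmalemma":
        plasmalemma_transporters = (Transporter(
            name="BicA", species="HCO3", source="outer",
            vmax_areal=vmax_b, km=km_b),)

    if organism == "land_plant":
        apo_pH = p.pH_apoplast if apoplast_pH is None else apoplast_pH
        membranes.append(Membrane(
            name="plasmalemma", inner="cytosol", outer="apoplast",
            permeabilities=_lipid_perms(p, p_co2_fold),
            transporters=plasmalemma_transporters))
        compartments.append(Compartment(
            name="apoplast", r_inner=p.r_cytosol,
            r_outer=p.apoplast_outer_radius, phase="aqueous", pH=apo_pH,
            ca_conc=p.CA_conc_apoplast if apoplastic_ca else 0.0))
        membranes.append(Membrane(
            name="wall_air", inner="apoplast", outer="substomatal",
            kind="gas_series"))
        compartments.append(Compartment(
            name="substomatal", r_inner=p.apoplast_outer_radius,
            r_outer=p.r_substomatal, phase="gas"))
        boundary = Boundary(
            kind="atmosphere",
            CO2_ppm=p.ext_CO2_ppm * external_co2_scale,
            O2_frac=p.ext_O2_frac,
            clamp_substomatal_ppm=clamp_substomatal_ppm)
    else:
        if apoplastic_ca or apoplast_pH is not None or clamp_substomatal_ppm:
            raise ValueError("apoplast/stomatal scenarios apply to the "
                             "land-plant models only")
        membranes.append(Membrane(
            name="plasmalemma", inner="cytosol", outer="boundary_layer",
            permeabilities=_lipid_perms(p, p_co2_fold),
            transporters=plasmalemma_transporters))
        compartments.append(Compartment(
            name="boundary_layer", r_inner=p.r_cytosol,
            r_outer=p.r_cytosol + p.delta_bl, phase="aqueous",
            pH=p.pH_external_water))
        co2_bulk = dissolved_from_ppm(
            p.ext_CO2_ppm, p.H_CO2, p.molar_volume_air) * external_co2_scale
        dic = equilibrium_dic(co2_bulk, p.pH_external_water, p)
        boundary = Boundary(
            kind="bulk_water", pH=p.pH_external_water,
            CO2_aq_uM=dic["CO2"], H2CO3_aq_uM=dic["H2CO3"],
            HCO3_aq_uM=dic["HCO3"],
            O2_aq_uM=dissolved_from_ppm(
                p.ext_O2_frac * 1e6, p.H_O2, p.molar_volume_air))

    scenario = dict(
        p_co2_fold=p_co2_fold, external_co2_scale=external_co2_scale,
        bica_location=bica_location, bica_vmax=vmax_b if bica_location else None,
        apoplastic_ca=apoplastic_ca, apoplast_pH=apoplast_pH,
        clamp_substomatal_ppm=clamp_substomatal_ppm)
    model = CellModel(
        model_id=model_id, organism=organism, has_pccm=has_pccm, params=p,
        compartments=tuple(compartments), membranes=tuple(membranes),
        lumen=lumen, boundary=boundary, scenario=scenario)
    model.validate()
    return model


def load_baseline(model_id: str) -> CellModel:
    """The published baseline configuration for one of the four models."""
    return build_model(model_id)


# ---------------------------------------------------------------------------
# perturbations and scenario grids
# ---------------------------------------------------------------------------

def perturb_parameters(params: ParameterSet, parameter_name: str,
                       relative_change: float) -> ParameterSet:
    """Scale exactly one parameter by (1 + relative_change).

    Deterministic; raises if the perturbed set violates an invariant
    (e.g. a porosity pushed above 1).
    """
    if not hasattr(params, parameter_name):
        raise ValueError(f"unknown parameter {parameter_name!r}")
    value = getattr(params, parameter_name)
    return params.replace(**{parameter_name: value * (1.0 + relative_change)})


def perturb_ensemble(params: ParameterSet, parameter_names: Sequence[str],
                     n: int, seed: int, log10_halfwidth: float = 0.5,
                     ) -> list[ParameterSet]:
    """Jointly jitter parameters log-uniformly for robustness testing.

    Each ensemble member scales every named parameter by an independent
    factor drawn log-uniformly from 10^±``log10_halfwidth``.  Members that
    would violate the parameter invariants are redrawn.
    """
    rng = np.random.default_rng(seed)
    out: list[ParameterSet] = []
    while len(out) < n:
        changes = {}
        for name in parameter_names:
            if not hasattr(params, name):
                raise ValueError(f"unknown parameter {name!r}")
            factor = 10.0 ** rng.uniform(-log10_halfwidth, log10_halfwidth)
            changes[name] = getattr(params, name) * factor
        try:
            out.append(params.replace(**changes))
        except ValueError:
            continue
    return out


_SCENARIO_KEYS = {"p_co2_fold", "external_co2_scale", "bica_location",
                  "bica_vmax", "bica_km", "apoplastic_ca", "apoplast_pH",
                  "clamp_substomatal_ppm"}


def scenario_grid(base_model: CellModel | str,
                  axes: Mapping[str, Iterable[Any]]) -> list[CellModel]:
    """Cartesian product of scenario variants of a base model.

    Axis names may be ParameterSet fields (the parameter is replaced) or
    scenario keywords of :func:`build_model`.  Each returned model carries
    its grid coordinates in ``model.scenario["coords"]``; ordering follows
    ``itertools.product`` over the axes in the order given.  Empty axes
    mapping returns the base model unchanged.
    """
    if isinstance(base_model, str):
        base_model = build_model(base_model)
    if not axes:
        return [base_model]
    names = list(axes.keys())
    value_lists = []
    for name in names:
        values = list(axes[name])
        if not values:
            raise ValueError(f"empty axis {name!r}")
        value_lists.append(values)
    base_scenario = {k: v for k, v in base_model.scenario.items()
                     if k in _SCENARIO_KEYS}
    models = []
    for combo in itertools.product(*value_lists):
        coords = dict(zip(names, combo))
        param_changes = {k: v for k, v in coords.items()
                         if hasattr(base_model.params, k)}
        scen = dict(base_scenario)
        for k, v in coords.items():
            if k in _SCENARIO_KEYS:
                scen[k] = v
            elif k not in param_changes:
                raise ValueError(f"unknown axis {k!r}")
        if scen.get("bica_location") is None:
            scen.pop("bica_vmax", None)
            scen.pop("bica_km", None)
        p = base_model.params.replace(**param_changes) if param_changes \
            else base_model.params
        model = build_model(base_model.model_id, params=p, **scen)
        tagged = dataclasses.replace(
            model, scenario={**model.scenario, "coords": coords})
        models.append(tagged)
    return models


# ---------------------------------------------------------------------------
# structured-text round trip
# ---------------------------------------------------------------------------

def parameters_to_yaml(params: ParameterSet) -> str:
    """Serialize a ParameterSet as a YAML document."""
    return yaml.safe_dump(params.as_dict(), sort_keys=True)


def parameters_from_yaml(text: str) -> ParameterSet:
    """Parse and validate a ParameterSet from YAML produced by
    :func:`parameters_to_yaml` (unknown keys are rejected)."""
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("expected a mapping of parameter names to values")
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    ps = ParameterSet(**data)
    ps.validate()
    return ps
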