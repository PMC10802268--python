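"""Spherically symmetric finite-volume discretization of a cell model.

The continuum model lives on concentric spherical shells; this module
discretizes each shell into radial nodes (uniform spacing within a
compartment), computes node volumes and interface areas analytically, and
emits the transport network the steady-state solver assembles:

* intra-compartment diffusion edges (D·A/Δr),
* membrane edges (permeability × area, in series with the half-cell
  diffusive conductances on either side),
* the land-plant wall/air entry (water-film + cell-wall conductances in
  series, with a Henry partition, over the air-exposed wall fraction),
* the stomatal feed of the well-mixed substomatal gas node,
* the algal bulk-water Dirichlet face,
* the lumped thylakoid-lumen node with its lateral (stroma) and end-cap
  (pyrenoid) couplings; tubule end caps cover n_tubules · π · r_tubule².

The gas space is always a single well-mixed node; gas-phase O2 is clamped
at its atmospheric value throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .params import (SPECIES, Boundary, CellModel, Membrane,
                     dissolved_from_ppm, hplus_micromolar, ppm_to_micromolar)

__all__ = ["RadialMesh", "Edge", "BoundaryEdge", "TransporterEdge",
           "build_mesh", "interface_conductance", "shell_volume"]

#: 1 µmol = 1e15 µM·µm³; converts areal µmol·µm⁻²·s⁻¹ to µM·µm·s⁻¹
UMOL_TO_UM3_UM = 1.0e15


def shell_volume(r_inner: float, r_outer: float) -> float:
    """Analytic volume of a spherical shell (µm³)."""
    return 4.0 / 3.0 * math.pi * (r_outer ** 3 - r_inner ** 3)


@dataclass(frozen=True)
class Edge:
    """Transport between two interior nodes.

    Flux a→b (µM·µm³/s) = G · (alpha_a·c_a − alpha_b·c_b).  The partition
    factors are 1 except on the gas side of a dissolution interface,
    where alpha is the Henry aqueous:gas coefficient.
    """
    a: int
    b: int
    species: str
    G: float
    alpha_a: float = 1.0
    alpha_b: float = 1.0
    tag: str = ""


@dataclass(frozen=True)
class BoundaryEdge:
    """Exchange between a node and a fixed external reservoir.

    Flux into the node (µM·µm³/s) = G · (c_ext_eff − c_node), where
    c_ext_eff already includes any Henry partition of the reservoir value.
    """
    node: int
    species: str
    G: float
    c_ext_eff: float
    tag: str = ""


@dataclass(frozen=True)
class TransporterEdge:
    """Unidirectional saturable pump moving species from src to dst node.

    Flux (µM·µm³/s) = Vmax_total · c_src / (Km + c_src).
    """
    name: str
    src: int
    dst: int
    species: str
    vmax_total: float  # µM·µm³/s at saturation (areal Vmax × area)
    km: float
    tag: str = ""


@dataclass
class RadialMesh:
    """Discretized model: nodes, volumes, reaction placement, transport."""
    model: CellModel
    r_lo: np.ndarray
    r_hi: np.ndarray
    r_center: np.ndarray
    volume: np.ndarray
    comp_name: list[str]
    is_aqueous: np.ndarray
    Hplus: np.ndarray            # µM, 0 for gas nodes
    ca_conc: np.ndarray          # µM, compartment-pH carbonic anhydrase
    lumen_ca_conc: np.ndarray    # µM, pyrenoid-hosted CA at lumen pH
    lumen_ca_Hplus: np.ndarray   # µM
    rubisco_vmax: np.ndarray     # local Vmax_carb (µM/s), 0 where absent
    edges: list[Edge] = field(default_factory=list)
    boundary_edges: list[BoundaryEdge] = field(default_factory=list)
    transporter_edges: list[TransporterEdge] = field(default_factory=list)
    lumen_node: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.volume)

    def nodes_of(self, compartment: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.comp_name)
                         if n == compartment], dtype=int)

    def compartment_volume(self, compartment: str) -> float:
        return float(self.volume[self.nodes_of(compartment)].sum())

    def to_table(self) -> pd.DataFrame:
        """Node table (radius, volume, compartment) for debugging dumps."""
        return pd.DataFrame({
            "r_center_um": self.r_center,
            "r_inner_um": self.r_lo,
            "r_outer_um": self.r_hi,
            "volume_um3": self.volume,
            "compartment": self.comp_name,
        })


def _sphere_area(r: float) -> float:
    return 4.0 * math.pi * r * r


def interface_conductance(model: CellModel, membrane: Membrane | str,
                          species: str) -> float:
    """Physical conductance (µm³/s) of a membrane interface for a species.

    Lipid membranes: permeability × spherical area (minus any tubule
    end-cap deduction).  The land-plant wall/air interface: water-film and
    cell-wall conductances in series over the air-exposed fraction of the
    wall area; only volatile species (CO2, O2) cross.  A species with no
    transport path has conductance 0 (valid, not an error).
    """
    if isinstance(membrane, str):
        (membrane,) = [m for m in model.membranes if m.name == membrane]
    p = model.params
    inner = model.compartment(membrane.inner)
    radius = inner.r_outer
    if membrane.kind == "gas_series":
        if species not in ("CO2", "O2"):
            return 0.0
        area = _sphere_area(radius) * p.airspace_fraction
        D = p.diffusivity(species)
        g_film = D * area / p.delta_water
        g_wall = D * p.eff_porosity * area / p.delta_wall
        return float(kinetics.series_conductance(g_film, g_wall))
    area = _sphere_area(radius) - membrane.area_deduction
    P = membrane.permeabilities.get(species, 0.0)
    return float(P * area)


def build_mesh(model: CellModel, nodes_per_compartment: int = 12) -> RadialMesh:
    """Discretize a CellModel; deterministic uniform node placement.

    ``nodes_per_compartment`` applies to every aqueous shell; the gas
    space is always one well-mixed node.
    """
    if nodes_per_compartment < 1:
        raise ValueError("nodes_per_compartment must be >= 1")
    p = model.params

    r_lo, r_hi, comp_name = [], [], []
    comp_first: dict[str, int] = {}
    comp_last: dict[str, int] = {}
    for comp in model.compartments:
        if comp.r_outer <= comp.r_inner:
            raise ValueError(f"zero-thickness compartment {comp.name}")
        n = 1 if comp.phase == "gas" else nodes_per_compartment
        bounds = np.linspace(comp.r_inner, comp.r_outer, n + 1)
        comp_first[comp.name] = len(r_lo)
        for k in range(n):
            r_lo.append(bounds[k])
            r_hi.append(bounds[k + 1])
            comp_name.append(comp.name)
        comp_last[comp.name] = len(r_lo) - 1

    r_lo = np.asarray(r_lo)
    r_hi = np.asarray(r_hi)
    r_center = 0.5 * (r_lo + r_hi)
    volume = 4.0 / 3.0 * math.pi * (r_hi ** 3 - r_lo ** 3)
    n_shell_nodes = len(r_lo)

    comp_by_name = {c.name: c for c in model.compartments}
    is_aqueous = np.array([comp_by_name[n].phase == "aqueous"
                           for n in comp_name])
    Hplus = np.array([hplus_micromolar(comp_by_name[n].pH)
                      if comp_by_name[n].pH is not None else 0.0
                      for n in comp_name])
    ca_conc = np.array([comp_by_name[n].ca_conc for n in comp_name])
    lumen_ca_conc = np.array([comp_by_name[n].lumen_ca_conc
                              for n in comp_name])
    lumen_ca_Hplus = np.array([
        hplus_micromolar(comp_by_name[n].lumen_ca_pH)
        if comp_by_name[n].lumen_ca_pH is not None else 0.0
        for n in comp_name])
    rubisco_vmax = np.array([
        p.Vmax_carb * comp_by_name[n].rubisco_vmax_factor
        if comp_by_name[n].rubisco else 0.0 for n in comp_name])

    mesh = RadialMesh(
        model=model, r_lo=r_lo, r_hi=r_hi, r_center=r_center, volume=volume,
        comp_name=list(comp_name), is_aqueous=is_aqueous, Hplus=Hplus,
        ca_conc=ca_conc, lumen_ca_conc=lumen_ca_conc,
        lumen_ca_Hplus=lumen_ca_Hplus, rubisco_vmax=rubisco_vmax)

    # --- intra-compartment diffusion ------------------------------------
    for comp in model.compartments:
        if comp.phase != "aqueous":
            continue
        first, last = comp_first[comp.name], comp_last[comp.name]
        for i in range(first, last):
            face = r_hi[i]
            dist = r_center[i + 1] - r_center[i]
            area = _sphere_area(face)
            for s in SPECIES:
                G = p.diffusivity(s) * area / dist
                mesh.edges.append(Edge(i, i + 1, s, G,
                                       tag=f"diff:{comp.name}"))

    # --- membrane interfaces --------------------------------------------
    atm_O2_gas = p.atm_O2_gas_uM
    for mem in model.membranes:
        i = comp_last[mem.inner]
        j = comp_first[mem.outer]
        r_m = comp_by_name[mem.inner].r_outer
        if mem.kind == "gas_series":
            # apoplast water <-> substomatal gas, volatile species only
            for s in ("CO2", "O2"):
                G = interface_conductance(model, mem, s)
                if G == 0.0:
                    continue
                H = p.H_CO2 if s == "CO2" else p.H_O2
                if s == "O2":
                    # gas-phase O2 clamped at atmosphere everywhere
                    mesh.boundary_edges.append(BoundaryEdge(
                        i, s, G, H * atm_O2_gas, tag=f"{mem.name}:{s}"))
                elif model.boundary.clamp_substomatal_ppm is not None:
                    c_gas = ppm_to_micromolar(
                        model.boundary.clamp_substomatal_ppm,
                        p.molar_volume_air)
                    mesh.boundary_edges.append(BoundaryEdge(
                        i, s, G, H * c_gas, tag=f"{mem.name}:{s}"))
                else:
                    mesh.edges.append(Edge(j, i, s, G, alpha_a=H,
                                           tag=f"{mem.name}:{s}"))
            continue
        area = _sphere_area(r_m) - mem.area_deduction
        for s in SPECIES:
            P = mem.permeabilities.get(s, 0.0)
            if P <= 0.0:
                continue
            # membrane in series with the half-cell diffusion on each side
            g_mem = P * area
            d_in = max(r_m - r_center[i], 1e-12)
            d_out = max(r_center[j] - r_m, 1e-12)
            g_in = p.diffusivity(s) * area / d_in
            g_out = p.diffusivity(s) * area / d_out
            G = kinetics.series_conductance(g_in, g_mem, g_out)
            mesh.edges.append(Edge(i, j, s, G, tag=f"{mem.name}:{s}"))
        for t in mem.transporters:
            src, dst = (j, i) if t.source == "outer" else (i, j)
            mesh.transporter_edges.append(TransporterEdge(
                name=t.name, src=src, dst=dst, species=t.species,
                vmax_total=t.vmax_areal * UMOL_TO_UM3_UM * area,
                km=t.km, tag=f"{mem.name}:{t.name}"))

    # --- external boundary ----------------------------------------------
    bc = model.boundary
    if bc.kind == "atmosphere":
        if bc.clamp_substomatal_ppm is None:
            sub = comp_last["substomatal"]
            area = _sphere_area(r_hi[sub])
            G = p.P_stomatal * area
            c_atm = ppm_to_micromolar(bc.CO2_ppm, p.molar_volume_air)
            mesh.boundary_edges.append(BoundaryEdge(
                sub, "CO2", G, c_atm, tag="stomata:CO2"))
    elif bc.kind == "bulk_water":
        last = comp_last["boundary_layer"]
        r_face = r_hi[last]
        area = _sphere_area(r_face)
        dist = r_face - r_center[last]
        fixed = {"CO2": bc.CO2_aq_uM, "H2CO3": bc.H2CO3_aq_uM,
                 "HCO3": bc.HCO3_aq_uM, "O2": bc.O2_aq_uM}
        for s in SPECIES:
            G = p.diffusivity(s) * area / dist
            mesh.boundary_edges.append(BoundaryEdge(
                last, s, G, fixed[s], tag=f"bulk:{s}"))
    else:
        raise ValueError(f"unknown boundary kind {bc.kind!r}")

    # --- thylakoid lumen --------------------------------------------------
    if model.lumen is not None:
        lum = model.lumen
        k = mesh.n_nodes
        mesh.lumen_node = k
        mesh.r_lo = np.append(mesh.r_lo, np.nan)
        mesh.r_hi = np.append(mesh.r_hi, np.nan)
        mesh.r_center = np.append(mesh.r_center, np.nan)
        mesh.volume = np.append(mesh.volume, lum.volume)
        mesh.comp_name.append("lumen")
        mesh.is_aqueous = np.append(mesh.is_aqueous, True)
        mesh.Hplus = np.append(mesh.Hplus, hplus_micromolar(lum.pH))
        mesh.ca_conc = np.append(mesh.ca_conc, 0.0)
        mesh.lumen_ca_conc = np.append(mesh.lumen_ca_conc, 0.0)
        mesh.lumen_ca_Hplus = np.append(mesh.lumen_ca_Hplus, 0.0)
        mesh.rubisco_vmax = np.append(mesh.rubisco_vmax, 0.0)

        for region, area_total, perms in (
                ("stroma", lum.lateral_area, lum.permeabilities_lateral),
                ("pyrenoid", lum.endcap_area, lum.permeabilities_endcap)):
            nodes = mesh.nodes_of(region)
            weights = mesh.volume[nodes] / mesh.volume[nodes].sum()
            for node, w in zip(nodes, weights):
                for s in SPECIES:
                    P = perms.get(s, 0.0)
                    if P <= 0.0:
                        continue
                    mesh.edges.append(Edge(
                        int(node), k, s, P * area_total * w,
                        tag=f"lumen_{region}:{s}"))

    return mesh
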