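"""Analysis drivers over the steady-state models.

Reproducible pipelines for the headline analyses: CO2 compensation
points, assimilation-versus-CO2 (A–Ci style) curves, BicA-pump ×
membrane-permeability sweeps, marginal-photon-cost ratios for adding a
pyrenoid CCM, cell-wall porosity scans, and one-at-a-time parameter
sensitivity tables.  Every driver returns tidy tables and flags
non-converged points instead of dropping them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .energetics import EnergeticsSummary, summarize
from .params import (CellModel, ParameterSet, _SCENARIO_KEYS, build_model,
                     dissolved_from_ppm, ppm_from_dissolved)
from .solver import SteadyStateSolution, solve_model

__all__ = ["SweepResult", "run", "model_variant", "compensation_point",
           "aci_curve", "bica_sweep", "marginal_cost_ratio",
           "marginal_cost_crossover", "porosity_scan", "sensitivity_table",
           "DEFAULT_SENSITIVITY_PARAMETERS"]


def run(model: CellModel, nodes_per_compartment: int = 12,
        initial_guess=None) -> tuple[SteadyStateSolution, EnergeticsSummary]:
    """Solve a model and summarize its energetics."""
    sol = solve_model(model, nodes_per_compartment=nodes_per_compartment,
                      initial_guess=initial_guess)
    return sol, summarize(sol)


def model_variant(model: CellModel, params: ParameterSet | None = None,
                  **scenario_overrides: Any) -> CellModel:
    """Rebuild a model with new parameters and/or scenario switches,
    preserving its other scenario settings."""
    scen = {k: v for k, v in model.scenario.items() if k in _SCENARIO_KEYS}
    scen.update(scenario_overrides)
    if scen.get("bica_location") is None:
        scen.pop("bica_vmax", None)
        scen.pop("bica_km", None)
    return build_model(model.model_id,
                       params=params if params is not None else model.params,
                       **scen)


def _with_external_ppm(model: CellModel, ppm: float) -> CellModel:
    """The same model with its external CO2 set to ``ppm`` (gas-phase ppm
    for the land plant; ppm-equivalent of the dissolved pool for the
    alga, whose whole DIC boundary re-equilibrates)."""
    p = model.params.replace(ext_CO2_ppm=ppm)
    return model_variant(model, params=p, external_co2_scale=1.0)


class _WarmStartRunner:
    """Re-solves a model family while warm-starting Newton from the last
    converged state (the mesh layout is identical across the family)."""

    def __init__(self, nodes_per_compartment: int = 12):
        self.nodes = nodes_per_compartment
        self._last: dict[str, np.ndarray] = {}

    def __call__(self, model: CellModel,
                 key: str = "") -> tuple[SteadyStateSolution, EnergeticsSummary]:
        guess = self._last.get(key or model.model_id)
        sol = solve_model(model, nodes_per_compartment=self.nodes,
                          initial_guess=guess)
        if not sol.converged and guess is not None:
            sol = solve_model(model, nodes_per_compartment=self.nodes)
        if sol.converged:
            self._last[key or model.model_id] = sol.c
        return sol, summarize(sol)


def compensation_point(model: CellModel | str,
                       bracket_ppm: tuple[float, float] = (0.5, 500.0),
                       tol_ppm: float = 0.05,
                       nodes_per_compartment: int = 12) -> float:
    """External CO2 (ppm) at which steady-state net fixation is zero.

    For the algal models the axis is the gas-phase ppm equivalent of the
    external dissolved CO2 (the whole pH-equilibrated DIC pool scales
    with it).  Brent root-finding on net fixation; raises if net fixation
    does not change sign across the bracket.
    """
    if isinstance(model, str):
        model = build_model(model)
    runner = _WarmStartRunner(nodes_per_compartment)

    def f(ppm: float) -> float:
        _, summary = runner(_with_external_ppm(model, ppm))
        return summary.net_fixation

    lo, hi = bracket_ppm
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"net fixation does not change sign on [{lo}, {hi}] ppm "
            f"(f={f_lo:.3g}, {f_hi:.3g})")
    return float(brentq(f, lo, hi, xtol=tol_ppm))


def aci_curve(model: CellModel | str, external_CO2_levels: Sequence[float],
              nodes_per_compartment: int = 12) -> pd.DataFrame:
    """Net fixation (and energetics) versus external CO2 (ppm axis).

    Levels must be positive and sorted ascending; each row carries its
    convergence flag.
    """
    if isinstance(model, str):
        model = build_model(model)
    levels = list(external_CO2_levels)
    if any(l <= 0 for l in levels):
        raise ValueError("CO2 levels must be positive")
    if levels != sorted(levels):
        raise ValueError("CO2 levels must be sorted ascending")
    runner = _WarmStartRunner(nodes_per_compartment)
    rows = []
    for ppm in levels:
        sol, summary = runner(_with_external_ppm(model, ppm))
        rows.append({"external_CO2_ppm": ppm,
                     "net_fixation": summary.net_fixation,
                     "rubisco_saturation": summary.rubisco_saturation,
                     "phi_CEF": summary.phi_CEF,
                     "phi_malate": summary.phi_malate,
                     "converged": sol.converged})
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """One record per grid point; nothing is silently dropped."""
    df: pd.DataFrame
    model_id: str
    meta: Mapping[str, Any] = field(default_factory=dict)


_SUMMARY_COLS = ("net_fixation", "rubisco_saturation", "phi_CEF",
                 "phi_malate", "ATP_demand", "photons_total_CEF")


def _record(summary: EnergeticsSummary, sol: SteadyStateSolution) -> dict:
    rec = {k: getattr(summary, k) for k in _SUMMARY_COLS}
    rec["converged"] = sol.converged
    return rec


def bica_sweep(organism: str, pump_location: str,
               permeability_folds: Sequence[float],
               vmax_levels: Sequence[float],
               external_co2_scale: float = 1.0,
               apoplastic_ca: bool = False,
               apoplast_pH: float | None = None,
               nodes_per_compartment: int = 12) -> SweepResult:
    """Grid of BicA Vmax × lipid-membrane CO2-permeability fold.

    ``pump_location`` is "chloroplast_envelope" or "plasmalemma";
    permeability folds are relative to the Gutknecht baseline value;
    ``vmax_levels`` are absolute areal Vmax values (µmol·µm⁻²·s⁻¹), 0
    meaning no pumping.  Apoplastic-CA and apoplast-pH switches apply to
    the land-plant plasmalemma scenario.
    """
    model_id = f"{organism}/no_pccm"
    runner = _WarmStartRunner(nodes_per_compartment)
    rows = []
    for fold in permeability_folds:
        for vmax in vmax_levels:
            kwargs: dict[str, Any] = dict(
                p_co2_fold=fold, external_co2_scale=external_co2_scale,
                bica_location=pump_location, bica_vmax=vmax)
            if organism == "land_plant":
                kwargs.update(apoplastic_ca=apoplastic_ca,
                              apoplast_pH=apoplast_pH)
            model = build_model(model_id, **kwargs)
            sol, summary = runner(model, key=f"fold={fold}")
            rec = {"p_co2_fold": fold, "bica_vmax": vmax}
            rec.update(_record(summary, sol))
            rows.append(rec)
    base = build_model(model_id)
    return SweepResult(df=pd.DataFrame(rows), model_id=model_id,
                       meta=dict(pump_location=pump_location,
                                 external_co2_scale=external_co2_scale,
                                 apoplastic_ca=apoplastic_ca,
                                 apoplast_pH=apoplast_pH,
                                 config_hash=base.config_hash()))


def marginal_cost_ratio(summary_pccm: EnergeticsSummary,
                        summary_no_pccm: EnergeticsSummary,
                        mode: str = "CEF") -> float:
    """Marginal photon cost of the extra fixation a PCCM buys, relative
    to the average photon cost without it.

    ratio = [(Photons_pccm − Photons_no) / (NetFix_pccm − NetFix_no)]
            / [Photons_no / NetFix_no]

    < 1 means the CCM is marginally light-efficient.  NaN when the PCCM
    does not increase net fixation (undefined marginal gain) or when the
    reference model fixes nothing.
    """
    attr = "photons_total_CEF" if mode == "CEF" else "photons_total_malate"
    ph_p, ph_n = getattr(summary_pccm, attr), getattr(summary_no_pccm, attr)
    nf_p, nf_n = summary_pccm.net_fixation, summary_no_pccm.net_fixation
    if nf_n <= 0 or ph_n <= 0:
        return float("nan")
    dnf = nf_p - nf_n
    if abs(dnf) < 1e-9 * max(abs(nf_p), abs(nf_n)):
        return float("nan")  # 0/0: no marginal change to price
    marginal = (ph_p - ph_n) / dnf
    average = ph_n / nf_n
    return marginal / average


def marginal_cost_crossover(organism: str,
                            bracket: tuple[float, float] | None = None,
                            tol: float = 0.5,
                            p_co2_fold: float = 1.0,
                            nodes_per_compartment: int = 12) -> float:
    """CO2 level at which the PCCM marginal-cost ratio crosses 1.

    For the land plant the axis is clamped substomatal CO2 (ppm; the
    CCM pays off below the returned value).  For the alga the axis is
    external dissolved CO2 (µM, pH-8.1-equilibrated pool; ``tol`` is then
    in µM).  Matched ±PCCM models are solved at identical boundary
    conditions and the ratio−1 root is bracketed by Brent's method.
    """
    runner = _WarmStartRunner(nodes_per_compartment)
    if organism == "land_plant":
        bracket = bracket or (120.0, 412.0)

        def ratio_minus_1(ppm: float) -> float:
            pair = []
            for mid in ("land_plant/pccm", "land_plant/no_pccm"):
                model = build_model(mid, p_co2_fold=p_co2_fold,
                                    clamp_substomatal_ppm=ppm)
                _, summary = runner(model, key=mid)
                pair.append(summary)
            return marginal_cost_ratio(pair[0], pair[1]) - 1.0
    elif organism == "alga":
        bracket = bracket or (1.0, 13.8)

        def ratio_minus_1(c_aq: float) -> float:
            ppm = ppm_from_dissolved(c_aq, ParameterSet().H_CO2)
            pair = []
            for mid in ("alga/pccm", "alga/no_pccm"):
                model = _with_external_ppm(
                    build_model(mid, p_co2_fold=p_co2_fold), ppm)
                _, summary = runner(model, key=mid)
                pair.append(summary)
            return marginal_cost_ratio(pair[0], pair[1]) - 1.0
    else:
        raise ValueError(f"unknown organism {organism!r}")

    lo, hi = bracket
    f_lo, f_hi = ratio_minus_1(lo), ratio_minus_1(hi)
    if not np.isfinite(f_lo) or not np.isfinite(f_hi) or f_lo * f_hi > 0:
        raise ValueError(
            f"marginal-cost ratio does not cross 1 on [{lo}, {hi}] "
            f"(f={f_lo:.3g}, {f_hi:.3g})")
    return float(brentq(ratio_minus_1, lo, hi, xtol=tol))


def porosity_scan(porosity_values: Sequence[float],
                  external_CO2_levels: Sequence[float] = (412.0,),
                  nodes_per_compartment: int = 12) -> SweepResult:
    """Land-plant ±PCCM energetics across cell-wall effective porosity.

    Porosities must lie in (0, 1]; each (porosity, external ppm, model)
    combination yields one record.
    """
    for eps in porosity_values:
        if not (0.0 < eps <= 1.0):
            raise ValueError("porosity must lie in (0, 1]")
    runner = _WarmStartRunner(nodes_per_compartment)
    rows = []
    for mid in ("land_plant/pccm", "land_plant/no_pccm"):
        for eps in porosity_values:
            for ppm in external_CO2_levels:
                p = ParameterSet().replace(eff_porosity=eps, ext_CO2_ppm=ppm)
                model = build_model(mid, params=p)
                sol, summary = runner(model, key=f"{mid}:{ppm}")
                rec = {"model_id": mid, "eff_porosity": eps,
                       "external_CO2_ppm": ppm}
                rec.update(_record(summary, sol))
                rows.append(rec)
    return SweepResult(df=pd.DataFrame(rows), model_id="land_plant/±pccm",
                       meta=dict(porosities=list(porosity_values),
                                 levels=list(external_CO2_levels)))


#: parameters surveyed by default in the local sensitivity analysis
DEFAULT_SENSITIVITY_PARAMETERS = (
    "Vmax_carb", "Km_CO2_rub", "Km_O2_rub", "kcat_ratio",
    "P_CO2", "P_HCO3", "P_H2CO3", "P_O2",
    "D_CO2_w", "D_HCO3_w", "k_hyd", "CA_kcat",
    "CA_conc_stroma", "CA_conc_cytosol",
    "g_s", "eff_porosity", "airspace_fraction", "delta_wall",
    "r_chloroplast", "r_cytosol",
)


def sensitivity_table(model: CellModel | str,
                      parameters: Iterable[str] | None = None,
                      default_perturbation: float = 0.10,
                      nodes_per_compartment: int = 12) -> pd.DataFrame:
    """One-at-a-time local sensitivity of saturation and quantum yield.

    Each parameter is scaled by ±``default_perturbation`` and the absolute
    % change of rubisco saturation and of φ(CEF) is reported.  The cytosol
    radius is perturbed by one tenth of the requested size and the
    response scaled by 10 (the full perturbation makes the outer shells
    geometrically inconsistent), assuming local linearity.  Rows that fail
    to converge are flagged rather than dropped.
    """
    if isinstance(model, str):
        model = build_model(model)
    names = list(parameters) if parameters is not None \
        else list(DEFAULT_SENSITIVITY_PARAMETERS)
    sol0, base = run(model, nodes_per_compartment)
    rows = [{"parameter": "baseline", "perturbation": 0.0, "scale": 1.0,
             "rubisco_saturation": base.rubisco_saturation,
             "phi_CEF": base.phi_CEF, "converged": sol0.converged,
             "d_saturation_pct": 0.0, "d_phi_pct": 0.0, "sign": 0}]
    for name in names:
        rel = default_perturbation
        scale = 1.0
        if name == "r_cytosol":
            rel = default_perturbation / 10.0
            scale = 10.0
        for sign in (+1, -1):
            try:
                p = model.params.replace(
                    **{name: getattr(model.params, name) * (1 + sign * rel)})
                variant = model_variant(model, params=p)
                sol, summary = run(variant, nodes_per_compartment)
                ok = sol.converged
                dsat = abs(summary.rubisco_saturation
                           - base.rubisco_saturation) \
                    / base.rubisco_saturation * 100.0 * scale
                dphi = abs(summary.phi_CEF - base.phi_CEF) \
                    / base.phi_CEF * 100.0 * scale
            except ValueError:
                ok, dsat, dphi, summary = False, float("nan"), float("nan"), None
            rows.append({
                "parameter": name, "perturbation": sign * rel, "scale": scale,
                "rubisco_saturation":
                    summary.rubisco_saturation if summary else float("nan"),
                "phi_CEF": summary.phi_CEF if summary else float("nan"),
                "converged": ok, "d_saturation_pct": dsat,
                "d_phi_pct": dphi, "sign": sign})
    return pd.DataFrame(rows)
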