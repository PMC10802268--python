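# Methods

## Scope and model structure

`ccmrd` models steady-state carbon assimilation in a single
photosynthesizing cell as a spherically symmetric reaction–diffusion
system. Four configurations are built in: a C3 land-plant mesophyll cell
and a green-algal cell, each with and without a pyrenoid-based
carbon-concentrating mechanism (PCCM). The spherical symmetry reduces
the problem to one radial dimension, which a finite-volume scheme
discretizes into nodes within concentric shell compartments:

| compartment | land plant | alga | notes |
|---|---|---|---|
| pyrenoid (PCCM only) | 0–1.0 µm | 0–1.0 µm | rubisco lives here |
| stroma | →4.63 µm | →4.63 µm | CA 270 µM, pH 8.0 |
| cytosol | →8.77 µm | →8.77 µm | CA 135 µM, pH 7.2 |
| apoplast water | →10 µm | — | pH 6.0; shell extended beyond its geometric 9.41 µm for numerical room |
| unstirred layer | — | →9.09 µm | pH 8.1 |
| substomatal airspace | →11.63 µm | — | single well-mixed gas node |

The thylakoid lumen of PCCM models is a lumped, well-mixed node
(six tubules of radius 0.5 µm and length 4 µm, V = 18.85 µm³, pH 6)
coupled to the stroma over the tubules' lateral membrane area
(75.40 µm²) and to the pyrenoid over their end caps (4.712 µm²), both
with lipid permeabilities plus the BLP bicarbonate-channel permeability.
The CA reaction that represents lumenal activity is placed in the
pyrenoid volume but evaluated at lumen pH and lumen CA concentration — a
deliberate simplification of tubules that penetrate the pyrenoid, kept
because it preserves where the CO2 is released while avoiding a resolved
tubule geometry.

## Species, reactions, and pH

CO2, H2CO3, HCO3⁻ and O2 are dynamic; H⁺ is not — each compartment's pH
is fixed and enters the rate laws as a constant. Consequences: proton
production/consumption by DIC chemistry is assumed buffered away, and
the CA equilibrium in each compartment is set by its pH through
`[HCO3⁻]/[CO2] = Keq/[H⁺]` (≈56 in the pH-8 stroma, ≈0.56 in the pH-6
lumen — the 100-fold ratio that powers the PCCM). Carbonate ion is
excluded; the reaction set covers only CO2/H2CO3/HCO3⁻.

Rubisco carboxylation and oxygenation are mutually competitive
Michaelis–Menten laws sharing one denominator structure; carbonic
anhydrase is a single reversible rate law; the uncatalysed hydration and
(de)protonation steps are first order with H2CO3 explicit. Oxygenation
consumes O2 only; the CO2 later released by photorespiration is **not**
re-injected into the spatial model (no respiration in the light either),
so at steady state the boundary carbon uptake equals the integrated
carboxylation flux exactly — this is checked in every solution's flux
audit. Net fixation `Vc − Vo/2` is evaluated on the fluxes afterwards.

## Boundary conditions

Land plant: a fixed atmosphere (412 ppm CO2, 0.2095 O2) feeds the
substomatal gas node through the stomatal conductance
(0.4375 mol m⁻² s⁻¹, converted with the 24.79 L/mol molar volume to an
equivalent gas-phase permeability of 10 845.6 µm/s over the substomatal
sphere). Gas enters the apoplast water through a series conductance of
the water film and the porous wall, `[(D·A/δ_w)⁻¹ + (D·ε·A/δ_cw)⁻¹]⁻¹`,
over the air-exposed half of the wall area, with a Henry partition; only
CO2 and O2 are volatile. The substomatal CO2 can instead be clamped (used
for the marginal-cost analysis). Gas-phase O2 is clamped at atmosphere
everywhere — O2 drawdown in air is negligible at these fluxes, while
aqueous O2 is fully dynamic.

Alga: the outside of a 0.32 µm unstirred boundary layer is a Dirichlet
face holding the bulk pools: a chosen dissolved CO2 with H2CO3 and HCO3⁻
at the pH-8.1 equilibrium implied by the uncatalysed rate constants
(air-equilibrated default: 13.8 µM CO2, ≈1040 µM HCO3⁻), and O2 at air
equilibrium. "X% external CO2" scenarios scale this whole pool.

Henry's law is handled with dimensionless aqueous:gas partition
coefficients at 25 °C — H_CO2 = 0.83, H_O2 = 0.032, both configurable —
so dissolution flux is `(D/δ)·(H·C_gas − C_aq)`.

## Energetics

Per carboxylation/oxygenation: 3 / 3.5 ATP and 2 NADPH. PCCM models add
the indirect cost of lumenal dehydration, `J_CA,lumen · 3/14` ATP (one
pmf proton per HCO3⁻ dehydrated; 14 protons per 3 ATP at the synthase).
Active bicarbonate pumping is charged 1 ATP per HCO3⁻ transported
(`ATP_per_bica`, configurable): the sweeps report several-fold increases
in ATP/CO2 with pumping, which is impossible if transport is free, and a
secondary active transporter's cost is of order one ATP equivalent. All
ATP costs enter total demand before the ATP:NADPH ratio is formed.

Photon pricing: one linear-electron-flow unit yields 2 NADPH and
12·(3/14) ≈ 2.571 ATP from 8 photons (these three bases are
configurable). The ATP deficit per unit, `Ratio·2 − 2.571` (floored at
zero), costs 0.43 photons/ATP via cyclic electron flow or
(2/5.45)·4 ≈ 1.468 photons/ATP via the malate valve. Note the printed
CEF constant 0.43 is kept as the default even though a 2 H⁺/photon CEF
at 14:3 H⁺:ATP would imply ≈2.33 photons/ATP; the constant is exposed
for exactly this reason. Quantum yield is `φ = (Vc − Vo/2)` over total
photons; φ(CEF) is the headline value, both modes are always computed.

Rubisco saturation is the integrated carboxylation flux as % of the
rubisco compartment's total capacity (Vmax × compartment volume). The
tabulated Vmax (7600 µM/s) applies to whichever compartment holds
rubisco, unscaled: two lines of evidence fix this reading — the PCCM
compensation points only make sense when the PCCM's absolute flux is two
orders of magnitude below the no-CCM model's (otherwise the supply
drawdown alone would floor them ~20× higher), and the algal
efficiency-crossover computed this way lands on the reference value.
The marginal-cost ratio
`[(Φ_pccm − Φ_no)/(N_pccm − N_no)] / [Φ_no/N_no]` is therefore usually a
quotient of two negative differences; it remains well defined and its
crossing of 1 bounds the CO2 region where the CCM is marginally
light-efficient.

## Parameter registry and reconciliations

All parameters live in one registry in canonical units (µm, s, µM,
µmol µm⁻² s⁻¹) with a machine-readable copy of the published baseline
table; a completeness test asserts every row maps to exactly one field
with the correct unit conversion. Three rows required reconciliation
against their own sources, recorded in the registry:

- **Rubisco Km rows are transposed as printed.** The printed assignment
  (Km_CO2 = 215 µM, Km_O2 = 8.6 µM) yields a rubisco specificity of 0.19
  and a compensation point near 21 000 ppm — incompatible with every
  downstream result. The cited tobacco kinetics give Kc ≈ 8.6 µM and
  Ko ≈ 215 µM dissolved at 25 °C, which reproduce the reported
  compensation behaviour; the registry uses Km_CO2_rub = 8.6 µM,
  Km_O2_rub = 215 µM.
- **CA Keq is read in molar units** (0.56 µM), agreeing within 7% with
  the equilibrium implied by the uncatalysed rate constants (0.6 µM);
  the literal mol/m³ reading is off by 10³ and would set CA and the
  spontaneous chemistry against each other at every pH.
- **Membrane O2 permeability** is listed at 75 cm/s — far above every
  other permeability; it is taken at face value (membranes are then
  effectively transparent to O2, which matches the flat O2 profiles in
  the solutions) but flagged here.

The starch sheath passes all three DIC species at 0.1·P_CO2 and O2 at
0.1·P_O2, exactly as tabulated (it is a porous, not lipid, barrier).
Values nowhere stated and therefore chosen here, all configurable:
Henry coefficients (above), the LEF bases (above), the apoplastic CA
concentration for its scenario (135 µM, the same "half the stroma"
convention the tabulated cytosol and lumen values use), and the BicA
ATP cost (above). Cytosolic pH 7.2 is used as printed.

## Numerics

- Finite volumes with uniform node spacing per compartment; node volumes
  are exact shell volumes (they telescope to the analytic compartment
  volume). Membrane fluxes are taken in series with the half-cell
  diffusive conductances on both sides; the wall/film series conductance
  stands alone at the gas boundary.
- Default 12 nodes per aqueous compartment: under node doubling, rubisco
  saturation and quantum yield move by ≈1% (the acceptance property
  requires <2%; 8 nodes sat marginally at 2.04% for the land-plant
  model). A solve is 150–200 unknowns and takes ~10 ms.
- Steady state by damped Newton with an analytic Jacobian (transport and
  fixed-pH interconversion assembled once as a linear operator; rubisco,
  CA and pumps contribute local blocks). Steps are damped to keep all
  concentrations positive and backtracked on residual growth; the
  convergence test is residual ∞-norm < 10⁻¹¹ × the gross flux scale.
  Pseudo-transient continuation (implicit Euler with a growing step) is
  the fallback; in practice Newton converges in 2–6 iterations from the
  boundary-equilibrated initial guess, and the solution is independent
  of the guess to ~10⁻⁹ relative.
- Root finding (compensation points, efficiency crossovers) uses Brent's
  method — 0.05 ppm tolerance on compensation points, with warm-started
  solves along the scan. All drivers are deterministic.

## What the scenario generator emulates — and does not

The registry's perturbation and grid machinery generates the study
conditions synthetically: one-at-a-time ±10% perturbations (cytosol
radius ±1% scaled ×10, since larger geometric perturbations collide with
the fixed outer shells), seeded log-uniform parameter ensembles for
robustness probes, and Cartesian scenario grids (permeability folds ×
pump Vmax, porosity decades, external-CO2 scalings). These exercise the
full pipeline without external data, but they are still *this* model's
conditions: fixed pH, spherical symmetry, a single cell, no light or
temperature response, no RuBP-regeneration (J_max) limit, no rubisco
activation state and no respiration in the light. Passing tests
demonstrate internal consistency and agreement with the reference
steady-state predictions — not validity for any real leaf or culture.

## Known limitations

- The pyrenoid micro-environment is sensitive to how strongly the lumen
  couples to it. This continuum model, solved to mesh convergence,
  drives the pyrenoid close to its thermodynamic ceiling
  (10^(pH_stroma − pH_lumen) ≈ 100× the stroma CO2) at low flux, which
  pushes the PCCM compensation points below 1 ppm — lower than
  voxel-based reference predictions of 2.7–6.2 ppm, whose own resolution
  studies show the pyrenoid concentrations rising with refinement. The
  no-CCM compensation points and both efficiency crossovers are
  insensitive to this and agree with the reference values to 8–18%.
- Chloroplast position, shape and surface-area ratios are outside the
  spherical geometry; so is any non-radial heterogeneity.
- The marginal-cost ratio is reported undefined (NaN) when the reference
  model fixes no carbon or the two models fix identically.
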