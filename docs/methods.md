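# Methods

This note documents the models behind `ferrokin`, the defaults and their
provenance, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Iron speciation from redox potential

In acidic (pH ≈ 1.5–2) sulfate liquors the Fe³⁺/Fe²⁺ couple poises the
platinum electrode, so the measured potential maps to the concentration
ratio through a Nernst relation

    Eh = E°′ + s·log10(r),   r = [Fe3+]/[Fe2+],   s = ln(10)·R·T/F,

with R = 8.314 J·mol⁻¹·K⁻¹, F = 96485 C·mol⁻¹, giving s ≈ 61.14 mV per
decade at 308.15 K (35 °C, the operating temperature; temperature is
fixed per calibration object). E°′ is an *effective* formal potential: a
single fitted parameter that absorbs activity coefficients, ionic
strength and sulfate complexation, none of which are separately
constrained by reactor monitoring data. Activity corrections and
pH-dependent (Pourbaix) effects are deliberately out of scope, as are
electrode junction corrections.

E°′ is calibrated from one (Eh, Fe(III) fraction) anchor:
E°′ = Eh − s·log10(f/(1−f)). The package default, **676.6 mV vs SHE**, is
the mean of the two values implied by the continuous-pilot steady states
(680 mV ↦ 53 % Fe(III) → 676.8 mV; 650 mV ↦ 27 % → 676.4 mV). That the
two independent anchors agree within 0.4 mV is itself a consistency check
of the Nernst form, and is asserted in the test suite. The fraction is
evaluated through a tanh/logistic form, numerically exact in [0, 1] for
arbitrarily extreme potentials.

## Rate estimators

Monitoring yields Fe(II)(t), either assayed or derived from Eh and total
iron (Fe(II) is preferred as the accounting basis because Fe(III) is
precipitation-prone). Two estimators:

- **max rate** = max over consecutive sample pairs of ΔFe(II)/Δt.
  "Consecutive" is the natural reading of daily monitoring; comparing all
  pairs would smooth the maximum away. Negative increments are retained —
  real traces are non-monotone — so the estimator can be negative on a
  purely decreasing series.
- **mean rate** = (Fe(II)_end − Fe(II)_start)/(t_end − t_start), by
  default over the full series; the choice of the "bioreduction period"
  endpoints (e.g. truncating at the plateau once Fe(III) is exhausted)
  belongs to the caller, and the synthetic pipeline truncates at 1 % of
  the initial Fe(III) charge.

Since the mean rate is the duration-weighted average of the consecutive
increment rates, max ≥ mean always; this is a property test.

## The biomass–rate law

Across batch and continuous experiments the volumetric bioreduction rate
is close to proportional to the planktonic cell density:
v = a·X_liq + b, fitted by unweighted OLS (no weighting scheme is
justified by the data; replicate structure is unknown). The fit is the
closed-form centred normal equations — numerically necessary because X
spans 1e8–5e9 cells·mL⁻¹ while v is O(10) — and is checked against
`numpy.polyfit` as an independent oracle. R² = 1 − SS_res/SS_tot, defined
as 1 when SS_tot = 0. The published 35 °C coefficients
(a = 3.46×10⁻⁹, b = 1.55, R² = 0.684) ship as a constant; note that
refitting the five summary-table (biomass, mean-rate) pairs alone gives
a ≈ 3.74×10⁻⁹ and b ≈ 1.06 — the published fit evidently included
additional points not enumerated in tabular form — so the package treats
the published law as data, not as a reproduction target. The intercept b
is the residual rate at zero planktonic biomass (abiotic reduction plus
attached, uncounted biomass); attached-biomass correction is a known
limitation, not modelled.

## Stoichiometry

Reactions are stored with exact `fractions.Fraction` coefficients
(the cell-synthesis reaction uses twentieths) and validated by exact
element and charge residuals, electrons counting as charge −1. Molar
couplings are *derived*, not hard-coded: formal oxidation states are
computed from composition and charge with O = −II, H = +I, so
S(0)→S(+VI) releases 6 e⁻, each reducing one Fe³⁺ — hence 6 Fe³⁺ per S⁰ —
and Mn(+IV)→Mn(+II) consumes 2 e⁻ from 2 Fe²⁺. The biomass C:N ratio
follows from the cell-synthesis coefficients, (1/5 + 1/20) C : 1/20 N
= 5:1; the ammonium demand of growth is the molar CO₂ fixation flux
(mass flux / 44.01 g·mol⁻¹) times the NH₄⁺:CO₂ coefficient ratio 1/4.
At the canonical CO₂ uptake of 40 mg·L⁻¹·h⁻¹ in a 2 L reactor this gives
0.454 mmol·h⁻¹. The aerobic sulfur oxidation
S⁰ + 3/2 O₂ + H₂O → SO₄²⁻ + 2 H⁺ is included for growth-reactor
bookkeeping; it is a package addition, not one of the four leaching
reactions. Thermodynamics (ΔG, equilibrium constants) and jarosite
stoichiometry are out of scope.

## Reactor models

All reactors are constant-volume and perfectly mixed; evaporation and
make-up water, gas–liquid transfer, pH/acid balance (K₂CO₃ control) and
oxygen dynamics are outside the state vector.

**Batch.** dFe2/dt = v, dFe3/dt = −v − k_precip·Fe3, biomass constant (no
anaerobic growth is observed in the liquid phase). The rate is clipped at
substrate exhaustion as v = min(v(X), Fe3/τ_clip), τ_clip = 1 h, which
keeps the right-hand side Lipschitz while sending v → 0 as Fe(III) runs
out; v is also floored at zero (the law's affine form could otherwise go
negative, and there is no anaerobic Fe(II) oxidant). Precipitation is a
single optional first-order Fe(III) sink (default off; no jarosite
chemistry); precipitated iron is an explicit state, so
Fe2 + Fe3 + Fe_precip is conserved to solver tolerance and reported as a
diagnostic.

**Growth reactor (R1).** dX/dt = µ·X·(1 − X/K) − X/HRT. Only steady-state
cell densities are observable, so µ and K are free parameters; defaults
µ = 0.1 h⁻¹, K = 2.31×10⁹ cells·mL⁻¹ put the chemostat steady state
X* = K(1 − 1/(µ·HRT)) at ≈2×10⁹ cells·mL⁻¹ for the stage-1 geometry.
µ·HRT < 1 is washout, flagged, not an error. Nutrients follow
dC/dt = (C_in − C)/HRT − q·X with per-cell uptake q (mg·L⁻¹·h⁻¹ per
cell·mL⁻¹), uptake suspended at depletion.

**Bioreduction reactor (R2).** Standard CSTR balances with inflows from
the R1 pulp and the Fe(III) concentrate (defaults 26.5 and 3 mL·h⁻¹,
22 g·L⁻¹ feed, 4 L); outflow equals total inflow. Biomass is a
conservative tracer (no anaerobic growth). The closed-form steady state
solves the linear system with v evaluated at X* = Q₁X_in/(Q₁+Q₂); when
the unclipped solution would drive Fe(III) negative, the
exhaustion-limited branch v = Fe3*/τ_clip applies (a documented switch,
verified against the transient integrator on both branches).

The volumetric bioreduction rate of a continuous reactor is defined as
the net Fe(II) production flux per liquid volume,
(q_out·Fe2_out − q_in·Fe2_in)/(1000·V). This definition is stated
prominently because the formula behind the reported pilot rates is not
documented and plausible alternatives (Fe2_out/HRT, an
Fe(III)-consumption basis) give different numbers; none reproduces the
reported stage-2 value from printed concentrations alone, so the reported
continuous rates are not used as numerical targets.

HRT is computed as V·1000/ΣQ. The nominal stage-1 growth-reactor HRT of
70 h is inconsistent with 2 L at 26.5 mL·h⁻¹ (→75.5 h); the package takes
volume and flow independently and reports the implied HRT. Likewise the
reported stage-2 R2 ammonium flux of 0.922 mmol·h⁻¹ and the R2 potassium
fluxes are not reproducible from the printed tables under any basis
tried, and are not asserted anywhere.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (stiffness-
switching), rtol 1e-8, atol 1e-10 mg·L⁻¹, fixed output grid; trajectories
are clipped at zero only to remove integrator-scale negative round-off.

## Nutrient fluxes

flux (mmol·h⁻¹) = (C_in − C_out)·(V/HRT)/M. The throughput basis V/HRT is
the default because it reproduces the reported stage fluxes with V = 2 L
and HRT 73/63 h (0.103 and 0.319 mmol·h⁻¹ for ammonium); a feed-rate
basis is available behind a flag for reactors where nominal flow and
realised HRT disagree. Release (outlet > inlet) yields a negative flux
and an explicit "release" note. When pH is held with K₂CO₃ the potassium
drop is confounded by base addition: the flux is still computed but
flagged and warned about. Separating microbial uptake from jarosite /
ammoniojarosite co-precipitation is not attempted — the measurements
cannot distinguish them.

## Synthetic data and what the tests show

The generator emulates the 35 °C study conditions: 4.5 g·L⁻¹ initial
Fe(III), 24 h sampling over 12 days (the Fe(II) plateau horizon), biomass
levels (3×10⁸, 2×10⁹, 5×10⁹) cells·mL⁻¹ spanning the batch experiments
and the richest continuous stage, with the published law as ground
truth. Measurement noise — no error model is reported for the original
instruments, so these are package assumptions — is Gaussian on Eh
(sd 5 mV, electrode-like) and multiplicative lognormal on cell counts
(σ = 0.15, counting-chamber error). The measured Fe(II) channel is
re-derived from the *noisy* Eh through the speciation map, reproducing
the error propagation of Eh-based monitoring. A 50 mg·L⁻¹ ferrous
carry-over from inoculum and medium keeps the initial potential finite.
All generators are pure functions of (parameters, seed); replicate
indices select independent substreams.

Recovery tests show: noiseless simulate → estimate → fit returns the
generating coefficients to better than 0.1 %; twenty noisy experiments
at the stated seed recover the slope within 10 %. These demonstrate the
*estimation pipeline's* correctness and noise robustness under the
assumed noise model — not that real reactors obey the affine law, nor
that attached biomass, precipitation variability, community shifts or
nutrient limitation (all real features the generator omits) would leave
the estimates unbiased.

Problem sizes throughout (trajectory grids of tens of points, tens of
replicates, simulation horizons of a few thousand hours) were chosen as
the smallest that exercise each property cleanly; steady-state assertions
use the closed forms wherever available rather than longer transients.

## Known limitations

- Single effective formal potential; no ionic-strength or speciation
  chemistry behind the Nernst map.
- The affine rate law is empirical; no saturation (Monod-type) term, no
  attached-biomass contribution.
- Precipitation is a lumped first-order sink, not jarosite equilibrium.
- Growth kinetics in R1 (µ, K) are conventions fitted to steady states,
  not measured quantities.
- The continuous-mode volumetric rate definition is the package's choice
  among undocumented alternatives (see above).
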