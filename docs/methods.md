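# Methods

This note documents the model, its assumptions, the tunable parameters,
and the design choices taken where the problem was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## PBPK model structure

Each compound occupies five well-stirred compartments: gut lumen, gut
wall, liver, central (plasma plus rapidly equilibrating tissue) and one
peripheral tissue. All amounts are in µmol, volumes in L, times in h;
doses are declared in mg and converted to µmol with the compound's molar
mass when the dosing schedule is compiled, so no unit arithmetic happens
inside the ODE core.

Tissues are perfusion-limited with venous equilibration: the outflow
concentration of a tissue is `C_tissue / Kp`. The liver receives the
gut-wall venous outflow (portal vein) plus a hepatic-artery supplement,
so an oral dose is subject to sequential gut-wall and hepatic first-pass
extraction. Absorption is first-order (`ka`, scaled by the dissolved
fraction); the blood/plasma ratio is fixed at 1. P-glycoprotein efflux is
a saturable gut wall → lumen flux; because the topology has no fecal
elimination, its net PK effect is on gut-wall residence time (and hence
gut-wall first-pass for CYP3A4 substrates), not on fraction absorbed — a
known simplification.

Default physiology ships as a versioned table
(`ddginet/data/physiology_defaults.csv`): per-kg organ volumes and
reference perfusion rates for a 73 kg adult (gut wall 50 L/h, hepatic
artery 20 L/h, peripheral 200 L/h). Volumes scale linearly with body
weight, flows with (BW/73)^0.75. The reference individual for dose
adaptation is a 30-year-old European male, 73 kg, 176 cm, all enzyme
multipliers 1.

### Driving concentrations

Every enzymatic rate and every perpetrator potency is driven by the
unbound concentration in the tissue where the enzyme resides,
`Cu = fu · C_tissue / Kp` (the venous-equilibrated unbound level). This
is declared explicitly because intracellular driving concentrations are
an assumption, not an observable.

### Interaction kinetics

Pathway rates are Michaelis–Menten, `v = Vmax_app·Cu/(Km_app + Cu)`, with

* competitive inhibition: `Km_app = Km · (1 + Σ Iu/Ki)`;
* noncompetitive inhibition: `Vmax_app = E_rel · Vmax / (1 + Σ Iu/Ki)`;

and one relative-amount state `E_rel` per enzyme–site pair obeying

```
dE/dt = kdeg · (1 + Σ_ind Emax·Iu/(EC50+Iu)) · Π_down (1 − Imax·Iu/(IC50+Iu))
        − (kdeg + Σ_mbi kinact·Iu/(KI+Iu)) · E
```

Baseline synthesis equals `kdeg`, so the unperturbed steady state is
exactly 1; clamped-inhibitor steady states have the closed forms
`kdeg/(kdeg+λ)` (inactivation), `1 + Emax·Iu/(EC50+Iu)` (induction) and
`1 − Imax·Iu/(IC50+Iu)` (down-regulation), which the tests verify against
the integrated engine. Down-regulation is implemented as Imax-type
suppression of synthesis — a declared stand-in, since no operational
equation for the mechanism is fixed by convention — and may coexist with
competitive inhibition by the same perpetrator (the bupropion-like mixed
case). Whether genotype scales enzyme abundance or turnover number is
observationally equivalent in this engine (a single multiplier on Vmax);
we do not claim to distinguish them.

### Genotype and population variability

CYP2D6 activity scores map linearly onto the abundance multiplier,
`multiplier = AS / 2`, making AS 2 (normal metabolizer, wild type) the
identity and AS 0 a null pathway. Phenotype labels use CPIC-style bands
(PM = 0, IM ≤ 1, NM ≤ 2.25, UM above). Virtual populations draw
demographics uniformly within stated ranges, scale physiology
allometrically, and draw per-enzyme abundance multipliers log-normally
with median 1 and geometric SD 1.3 by default (configurable per enzyme);
the AS factor multiplies the CYP2D6 draw. Populations are bitwise
reproducible from their seed.

## Numerics

LSODA (scipy `solve_ivp`) with event-exact dosing: integration restarts
at every dose time and samples coinciding with a dose are recorded
post-dose. Default tolerances are rtol 1e-8 / atol 1e-10 µmol; the dose
search uses rtol 1e-6 (its objective is a ratio of identically computed
AUCs). Small negative excursions are clipped to zero at window
boundaries; clipping beyond 10·atol raises a warning. Mass balance —
dose = in-system + cumulative eliminated, with metabolic flux counted as
parent elimination — holds to ≤ 1e-6 relative at the default tolerances.
The right-hand side has two interchangeable implementations (vectorized
numpy and a numba-compiled scalar kernel) verified identical to machine
precision; numba is optional but ~30× faster.

Steady state under repeated dosing is declared when consecutive
victim-interval AUCs differ by < 0.5% relative, capped at 50 intervals
(capped runs are flagged, never silent). Non-compartmental metrics use
the linear trapezoid exclusively — defined on observed grids containing
zeros — with no extrapolation to infinity.

## Evaluation statistics

Effect PK ratios divide the exposure under a variant condition (genotype
and/or co-medication) by its reference (AS 2 and/or monotherapy). GMFE
uses the absolute-value convention `10^(Σ|log10(pred/obs)|/n)`: every
fold error is ≥ 1 and the statistic is invariant under swapping predicted
and observed. Prediction-success limits follow the observed-ratio-
dependent form `L = (δ + 2(R−1))/R` evaluated on `max(R, 1/R)` with
acceptance interval `[R/L, R·L]`; δ = 1.25 encodes the 20% variability
margin (interval [0.80, 1.25] at R = 1) and the bounds widen toward the
classical twofold range for large effects. Population profile summaries
use geometric means, matching how observed means are typically reported.

## Dose adaptation

The reference exposure is the victim's steady-state AUC at the original
dose, reference individual, AS 2, monotherapy. Candidate doses live on a
fixed grid — 1,…,99, 100, 110,…,500 percent of original (the asymmetric
step sizes reflect that interaction scenarios mostly require reductions;
the 500% ceiling is configurable headroom). "Optimally aligned" is
operationalized as minimizing |log(achieved AUC_ss / reference)| on the
grid, ties broken toward the smaller dose. The default search warm-starts
at the linear-PK inverse of the unadapted fold change, brackets the sign
change of the log-ratio by geometric expansion and bisects; for monotone
dose–exposure relations it provably returns the exhaustive-search answer,
and the test suite checks that equivalence scenario by scenario.
Nonlinear victims make percent-dose and fold-change non-reciprocal; the
grid search, not the linear inverse, is authoritative. Matching is on
AUC_ss only; recommendations record the achieved ratio and an explicit
80–125% bioequivalence flag.

## Synthetic world

No real compound parameterizations or clinical profiles ship with this
package; the generator produces mechanistic stand-ins.

* **Archetypes.** Parameter ranges per kind are in
  `ARCHETYPE_RANGES`. Substrate fm targets follow the FDA sensitivity
  categories (sensitive ≈ 0.85–0.95 via CYP2D6, moderate ≈ 0.4–0.6 with
  CYP3A4 co-clearance and P-gp efflux). fm is *defined operationally* as
  the CYP2D6 share of total clearance flux for the reference individual
  at sub-Km concentrations, computed by flux accounting during an IV
  tracer simulation; substrate Vmax values are calibrated until the
  realized fm matches the drawn target (< 0.5%). Renal clearance ranges
  are stated as plasma clearance and divided by fu internally, pinning
  the poor-metabolizer half-life of a sensitive substrate near 20 h —
  the scale observed for clinical sensitive substrates.
* **Fixture network.** Six compounds, three enzymes (CYP2D6 liver,
  kdeg 0.02 /h ≈ 35 h half-life; CYP3A4 gut+liver 0.03 /h; P-gp gut
  0.03 /h), seven edges covering all five mechanisms, one tracked
  metabolite, and a curated scenario list (reference, DGI, DDI, DDGI for
  the sensitive victim; reference and CYP3A4 DDI for the moderate one).
* **Virtual studies.** Every arm is simulated over the *same* paired
  population (shared seed; arms differ only in AS and co-medication,
  like a crossover design), and the "observed" profile is the population
  geometric mean times independent multiplicative log-normal noise per
  sampling point — a surrogate for digitization plus assay error,
  chosen as the simplest model consistent with strictly positive
  concentrations. The truth block stores the noiseless means, the full
  generator configuration and all seeds, sufficient for bit-identical
  re-simulation. Studies default to 32 individuals per arm: a deliberate
  desk-scale stand-in for the 1,000-individual populations typical of
  network evaluation (population-level conclusions are correspondingly
  noisier).
* **fm recovery.** `fm = 1 − AUC_NM/AUC_PM` is exact for IV dosing and
  linear kinetics; the shipped recovery design therefore uses a low IV
  dose (oral dosing confounds the ratio through phenotype-dependent
  first-pass for high-extraction substrates, and therapeutic-size doses
  transiently saturate the pathway). The bootstrap interval resamples
  sampling-point observation noise only.

What a green test does **not** establish: the archetypes do not mimic any
specific drug's absolute PK; observation noise is independent across
points (real digitized profiles have correlated errors); populations lack
age-dependent enzyme ontogeny, ethnicity-specific physiology and
transporter pharmacogenetics; and the engine omits enterohepatic
recirculation, permeability-limited tissues and active hepatic uptake.

## Known limitations

Victims that are themselves perpetrators are supported by the engine
(all compounds integrate simultaneously) but not exercised by the
fixture. The steady-state criterion can fire early for drugs whose
accumulation half-life far exceeds the dosing interval; the interval cap
and convergence flag make this visible. The 5-compartment topology
cannot represent organ-specific exposure beyond gut/liver.
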