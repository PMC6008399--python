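# Methods

This note records the models implemented in `mdhflux`, their
assumptions, the defaults that matter, and what the synthetic-data
tests do and do not establish about real measurements.

## Reaction thermodynamics

The reaction is CH3OH + NAD⁺ ⇌ CH2O + NADH + H⁺ with standard
transformed Gibbs energy ΔG°′ = +34.2 kJ mol⁻¹ (user-overridable;
`thermo.DG0_METHANOL_OXIDATION`).  ΔG = ΔG°′ + RT ln Q with
R = 8.3145×10⁻³ kJ mol⁻¹ K⁻¹ and a default temperature of 310.15 K
(assays run at 37 °C).  Concentrations are molar internally; the
CSV-facing layer works in µM because that is how formaldehyde is
reported.  Two deliberate simplifications:

- activities equal concentrations (no ionic-strength or activity
  coefficient corrections), and
- formaldehyde is one pool: no hydration equilibrium between CH2O and
  methanediol is modelled, which matches what a Nash assay of the
  supernatant measures.

Because of these, the generic equilibrium solver gives
[CH2O]_eq ≈ 13.6 µM at 250 mM methanol and NAD:NADH = 31.3 — the right
order of magnitude for the tens-of-µM ceiling that makes the pathway
marginal, but not a calibrated absolute number.  Tests therefore assert
order of magnitude only, and nothing in the package hard-codes a
particular equilibrium value as truth.

## The paired-steady-state bound

With matched treatment of an Mdh-only strain (index 1) and a
full-pathway strain (index 2), and the Mdh-only strain assumed at or
below equilibrium (formaldehyde is reactive, so ΔG₁ ≤ 0):

    ΔG₂ ≤ RT ln([CH2O]₂/[CH2O]₁)  ⇒  J⁺/J⁻ ≥ [CH2O]₁/[CH2O]₂,

after multiplying by the ratio of NAD:NADH ratios when both strains
carry one (the correction cancels when redox states match).  This is a
*bound*, never a point estimate; `ReversibilityEstimate.bound_kind`
keeps the distinction explicit so downstream consumers can distinguish
guaranteed-forward fraction from maximum-possible reverse flux.

## KIE flux partitioning

From the mass balance d[F]/dt = k₁[NAD][CH3OH] − k₋₁[NADH][F] −
k₂[Ru5P][F], the steady state is [F]ss = k₁[NAD][CH3OH]/(k₋₁[NADH] +
k₂[Ru5P]).  Writing α = k₁H/k₁D (primary KIE, default 3.2),
γ = K_H/K_D (equilibrium isotope effect, default 1.07, from the
literature on NAD-dependent primary alcohol oxidation) and
β = k₂[Ru5P]/(k₋₁[NADH]), the deuterated channel has k₁D = k₁H/α and
k₋₁D = γk₋₁H/α, giving R = (γ + αβ)/(1 + β).  Inverting:

    β = (γ − R)/(R − α),   MDH_F/MDH_R = 1 + β,
    forward fraction = (1 + β)/(2 + β) = (γ − α)/(γ + R − 2α).

Assumptions: methanol, NAD⁺, NADH and Ru5P pools are unchanged between
the H and D experiments, and the secondary KIE of the sink enzyme
(~1.04) is negligible.  The secondary effect is stored and an optional
numeric mode (`predicted_ratio_from_kinetics(..., apply_secondary=True)`)
re-derives R with k₂D = k₂H/1.04 for sensitivity analysis; across the
valid domain it shifts R by under 2%.

α > γ is enforced at construction — it is what makes R a strictly
increasing readout of β and bounds R to [γ, α].  Measured ratios
outside that window (possible under noise; one study condition sat
exactly on the α boundary) are handled by an explicit per-call policy:
`strict` raises, `clamp` projects to the nearest endpoint and records a
flag, and the Monte-Carlo propagation clamps per draw and reports the
clamped fraction.  The batch pipeline defaults to clamp-with-flags.
Conditions whose formaldehyde pools were too low to measure an H/D
ratio are marked indeterminate, never imputed.

Percent reporting rounds half-up to integer percent (the presentation
convention for these numbers); raw fractions are always retained.

## Uncertainty propagation

Reversibility bounds and KIE partitions are ratios of noisy positive
quantities, which are skewed, so the default interval is seeded Monte
Carlo (Gaussian draws at the stated means/sds, invalid draws dropped,
error raised if more than half are invalid).  The reported interval is
mean ± sd of the resampled estimator — matching the ±sd convention of
the source measurements — with 2.5/97.5 percentiles also returned.  A
first-order delta method is kept as a cross-check and agrees with the
Monte-Carlo sd to ~10% in the regimes exercised.

## Dynamics and the enzyme-dose scan

The formaldehyde ODE is linear with relaxation rate λ = k₋₁[NADH] +
k₂[Ru5P]; F(t) = F_ss(1 − e^{−λt}) + f₀e^{−λt} serves as the oracle
for both integrators.  `euler` reproduces the fixed-step explicit
scheme with the reference step dt = 0.002 (arbitrary time units) and
refuses dt·λ ≥ 2; `adaptive` wraps an RK45 integration at rtol 1e-10
and matches the closed form to better than 1e-6 relative.

"Increasing the Vmax" of the dehydrogenase is interpreted as increasing
the enzyme dose, scaling k₁ *and* k₋₁ together — a catalyst accelerates
both directions.  This is the reading under which the regime dichotomy
is a theorem of the steady-state expression: the sink-flux gain under a
dose factor c is c(k₋₁B + k₂C)/(ck₋₁B + k₂C) (B = [NADH], C = [Ru5P]),
which tends to 1 near equilibrium (k₂C ≪ k₋₁B) and to c far from it.
Scaling k₁ alone would scale F_ss proportionally in both regimes and
erase the diagnostic; that mode is available as `k1_only` for contrast,
and the assumption is recorded in output metadata.  The underlying
simulation parameters are dimensionless (k₁[NAD][CH3OH] = 1, β set by
scenario), so dose-scan conclusions are regime-level, not numeric
reproductions of any particular published trace.

Steady-state detection fits a slope over the last 5 samples and
extrapolates it over the full elapsed time; a trace is "at steady
state" when that projected relative change is below 2%.  Extrapolating
over the whole run, not just the window, is what makes a trace
truncated at one relaxation time fail the check even though successive
samples differ little.

## Enzyme assays

Michaelis–Menten fits use nonlinear least squares seeded from a
Lineweaver–Burk line with a fixed fallback-start grid (deterministic),
and report t-based confidence intervals from the asymptotic covariance
at the optimum — the standard nlinfit/nlparci-style contract.  Coverage
is validated by seeded simulation (≥ 90% at nominal 95% over repeated
noisy plates at the six assay substrate levels, 6–300 mM).  The KIE
from paired H/D plates is defined as Vmax_H/Vmax_D (a single number, as
Michaelis-plot analyses report), with a per-substrate-level velocity
ratio diagnostic available to expose any Km isotope effect.  Nash
calibration (0–100 µM standards, A412) keeps a free intercept because
blank wells drift; forcing through the origin is recorded on the curve.
Initial rates from A340 traces use the longest prefix with linear
r² ≥ 0.99 (minimum 4 points) and convert by Beer–Lambert
(ε₃₄₀ = 6220 M⁻¹cm⁻¹) or through an NADH standard curve.

## Isotopomer handling

Natural-abundance correction is the binomial-convolution matrix method
(carbon only, 13C abundance 0.0107): column j of the matrix distributes
j labeled carbons plus binomial natural labeling over the remaining
n − j positions; an optional tracer-purity factor (default 0.99 for
13C-methanol when enabled) convolves a second binomial over the labeled
positions.  The system is solved by non-negative least squares, so
noise-induced negative components are absorbed; the clipped mass is
reported as a flag.  Whether published enrichment values were computed
before or after purity correction is not always stated, so both modes
are exposed and the default leaves purity at 1.0.  Mean enrichment is
Σᵢ i·Mᵢ/n; F6P is treated as a 6-carbon metabolite in the labeling
workflow.

## Constraint-based analysis

The three heterologous reactions (Mdh, Hps, Phi) plus passive methanol
diffusion are defined with full formulas and checked elementally
(C, H, O, N, P) before being grafted onto any cobra model.  The bundled
toy network (built in code, SBML round-trip tested) lumps glycolysis,
pentose-phosphate rearrangement and respiration into ~13 reactions with
exact carbon bookkeeping but deliberately coarse proton/phosphate
accounting; it grows on glucose natively and on methanol only when all
three added reactions are present, making knockout essentiality and
uptake matching testable as LP facts.  Uptake matching bisects the
exchange bound for the smallest uptake whose optimal growth is within a
2% default tolerance of the target.  "Proportional flux" is normalised
per carbon-mole of substrate uptake — the choice that makes a 6-carbon
and a 1-carbon feed comparable — and comparisons across alternate
optima should use the provided flux-variability ranges rather than a
single optimum.

## Synthetic data and what passing tests show

Generators are pure functions of their seed.  Paired H/D experiments
invert the framework exactly as the analysis assumes: β from the target
forward fraction, k₋₁[NADH] = 1, k₂[Ru5P] = β, deuterated constants via
α and γ, timecourses to 12/λ, multiplicative log-normal noise
(mean-preserving, parameterised by CV, default 5% — plate-reader
concentration readouts are positive and CV-dominated; replicate count
defaults to 3 as in the source measurements).  The bundled fixture
table carries the printed study values (fold reductions 1.2 ± 0.1,
4.7 ± 1.7, 3.0 ± 0.3; H/D ratios 1.5 ± 0.3 and 3.2 ± 0.4; 52/17 µM and
56 µM steady states) in a wide "ratio layout", because the published
fold ratios survive where some raw concentrations do not; the pipeline
equally accepts the long per-strain CSV layout.

Because the generator and the analysis share the same lumped two-step
model, recovery tests establish correctness of the inference given the
model — not that real cells obey it.  In particular the generator does
not emulate spatial formaldehyde gradients, pool-size drift between H
and D experiments, instrument baselines, or deviations from mass-action
kinetics; conclusions about real strains rest on the model assumptions
stated above.  Recovery studies use forward fractions {0.55…0.95} at
5% noise with 200 seeded repetitions (40 per grid point) — sized so the
whole suite runs in well under a minute while the median recovery error
estimate is stable.

## Known limitations

- The thermodynamic bound inherits the at-or-below-equilibrium
  assumption for the Mdh-only strain; if that strain were far from
  equilibrium the bound would be conservative, never anti-conservative.
- No mechanistic NADH-inhibition model is fitted (the inhibition mode
  is not resolved by the available data); only fractional inhibition
  summaries are provided.
- The isotope framework is exactly the two-step lumped system; it does
  not extend to branched isotope networks.
- Equilibrium-concentration predictions are uncorrected for activity
  coefficients and should be read as order-of-magnitude.
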