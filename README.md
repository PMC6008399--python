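# mdhflux

Diagnostics for engineered methanol assimilation: is flux through
NAD-dependent methanol dehydrogenase (Mdh) limited by thermodynamics or
by enzyme kinetics?

## The problem

Synthetic methylotrophy grafts Mdh plus the ribulose-monophosphate (RuMP)
entry enzymes — hexulose phosphate synthase (Hps) and phosphohexulose
isomerase (Phi) — onto a host such as *E. coli*.  The first step,

    CH3OH + NAD+  <->  CH2O + NADH + H+        ΔG°′ = +34.2 kJ mol⁻¹,

is steeply uphill, so net forward flux exists only while formaldehyde is
kept far below its equilibrium concentration by the downstream sink.
Strain engineers need to know which regime a strain is in: near
equilibrium (improve formaldehyde consumption) or kinetically limited
(improve Mdh itself).  `mdhflux` implements two complementary in-vivo
readouts plus the supporting assay and simulation tooling:

1. **Paired-steady-state thermodynamic bound.**  Comparing steady-state
   formaldehyde in an Mdh-only strain (at or below equilibrium) with the
   full-pathway strain bounds the flux ratio via the flux–force relation
   ΔG = −RT ln(J⁺/J⁻):

       J⁺/J⁻ ≥ [CH2O]_MdhOnly / [CH2O]_FullPathway,

   giving a guaranteed *minimum* forward-flux fraction r/(1+r) without
   knowing ΔG°′ or the intracellular methanol concentration.

2. **Kinetic-isotope-effect (KIE) partition.**  Feeding CD3OD slows the
   Mdh forward step by the primary KIE α = k_H/k_D ≈ 3.2, while the
   equilibrium isotope effect is only γ ≈ 1.07.  The steady-state ratio
   R = [CH2O]ss/[CD2O]ss of the lumped mass-action system
   d[F]/dt = k₁[NAD][CH3OH] − k₋₁[NADH][F] − k₂[Ru5P][F] satisfies

       R = (γ + αβ)/(1 + β),     β = k₂[Ru5P]/(k₋₁[NADH]),

   so a single measured R in [γ, α] yields a *point estimate* of the
   forward fraction (1+β)/(2+β) = (γ − α)/(γ + R − 2α).

The package also provides formaldehyde ODE simulation with a closed-form
oracle and enzyme-dose scans, Michaelis–Menten/KIE fitting with t-based
confidence intervals, Nash-assay calibration, mass-isotopomer
natural-abundance correction and enrichment, constraint-based model
amendment (cobrapy), and seeded synthetic-data generators with known
ground truth for every input.

## Worked example

The bundled fixture table holds the printed study conditions
(fold reductions in steady-state formaldehyde, H/D ratios, α = 3.2,
γ = 1.07).  The unsupplemented full-pathway condition measured
R = 1.5 ± 0.3:

```bash
$ mdhflux kie-fraction --ratio 1.5 --ratio-sd 0.3 --seed 1
{
  "R": 1.5,
  "beta": 0.25294117647058817,
  "forward_fraction": 0.556135770234987,
  "forward_percent": 56,
  "interval": [0.5176755815886628, 0.6028743693822666],
  "clamp_fraction": 0.0759,
  "flags": []
}
```

The sink flux is only ~0.25× the reverse Mdh flux (β), so just 56% of
the total Mdh flux runs forward — the pathway is close to equilibrium.
`clamp_fraction` reports how often Monte-Carlo draws of the noisy ratio
left the physical window [γ, α].  Under glycolysis inhibition with
FBPase (glpX) overexpression, formaldehyde dropped 3.0 ± 0.3-fold when
the sink enzymes were present, and the thermodynamic bound gives:

```bash
$ mdhflux thermo-bound --fold-ratio 3.0 --fold-ratio-sd 0.3 --seed 1
{
  "flux_ratio_lower": 3.0,
  "forward_fraction_lower": 0.75,
  "forward_percent": 75,
  "interval": [0.7291545348439713, 0.7675739681872656],
  "method": "paired_steady_state_bound",
  "flags": []
}
```

i.e. at least 75% of the Mdh flux is guaranteed forward.  The full
per-condition report (thermodynamic bounds, KIE estimates, indeterminate
conditions, provenance) comes from:

```python
from mdhflux import run_reversibility_analysis, synthetic

report = run_reversibility_analysis(synthetic.paper_fixture_table(), seed=0)
print(report.to_json())
```

or `mdhflux analyze observations.csv` on your own table (long layout:
condition, pathway, isotope, formaldehyde_uM, …; or the wide ratio
layout of the fixture).

## Scope notes

- ΔG°′ is a user input; no component-contribution estimation is done,
  and activities are taken equal to concentrations.
- The dynamics module models exactly the lumped two-step system above;
  Ru5P is an exogenous constant, not a full RuMP-cycle model.
- Genome-scale FBA runs accept any SBML model; tests use a bundled
  ~20-reaction toy network so nothing is downloaded.
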