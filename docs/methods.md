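# Methods

## Scope and model structure

`raasim` simulates the circulating (endocrine) renin–angiotensin–
aldosterone system (RAAS) over a reduced whole-body physiology, together
with the pharmacokinetics of oral enalapril (Ena) and its active
metabolite enalaprilat (Enaat), and the pharmacodynamic coupling between
the two: Enaat reversibly sequesters endothelial angiotensin-converting
enzyme (ACE), throttling the conversion of angiotensin 1 (Ang1) to
angiotensin 2 (Ang2) and thereby the downstream aldosterone signal and
the upstream renin feedback.

The body is a graph of plasma compartments: an arterial pool feeding 15
organ compartments in parallel, collecting in a venous pool that perfuses
the lung before returning to the arterial pool.  Placing the lung in
series means its endothelial ACE (100% relative expression) sees total
cardiac output, which is what makes pulmonary conversion dominant.  The
"Plasma" entry of the expression table is modelled as a rest-of-body
peripheral plasma compartment carrying its 6% ACE expression; the venous
and arterial pools are pure transit volumes.  All RAAS species circulate
in plasma only; membrane-bound targets (ACE, AT1) do not circulate and
exist as per-organ pools set by relative expression,
`C0 = C_Ref · E_Ref / 100`.

### Rate laws

With concentrations in µmol/L, volumes in L and time in min:

| process | form |
|---|---|
| convection | `Q_organ · (1 − HCT) · C_pls` |
| cellular secretion (AGT, prorenin) | `k_Secretion · C_cell` |
| prorenin → renin activation (kidney) | `V_MaxKid · V_Kidney · C_pro / (C_pro + K_mKid (1 + C_Ang2/K_inh))` |
| degradation (every plasma litre) | `C · ln 2 / t_1/2` |
| enzymatic conversion (renin·AGT, ACE·Ang1) | `k_cat · V0 · C_enzyme · C_pro / (C_pro + K_m)` |
| reversible binding (Ang2–AT1, Enaat–ACE) | `k⁺ C_target C_ligand − k⁻ C_complex` |
| aldosterone synthesis | `k_Secretion · C_complex + k_Production` |
| hepatic Ena → Enaat hydrolysis | `V_maxLiv · V_Liver · C_Ena / (C_Ena + K_mLiv)` |

Enzymes are catalytic (renin and ACE are not consumed by conversion); ACE
is removed from the catalytic pool only by Enaat binding.  Species bound
in a complex are protected: complexed Ang2 does not degrade and complexed
Enaat does not clear, which is exactly the mechanism behind Enaat's
prolonged terminal phase.

## Reduced physiology

Per-organ plasma volumes and blood flows come from a packaged
reference-human table (`data/reference_physiology.csv`): 3.2 L total
plasma and ~6.4 L/min whole-blood cardiac output at 70 kg, split over the
organ roster with conventional perfusion fractions, scaled linearly with
body weight.  Hematocrit defaults to 0.47 (adult male).  These absolute
volumes and flows are a design choice of this package — steady-state
hormone balances depend mostly on total plasma volume and relative
expression, both of which the table preserves — and users can override
any row from configuration.  Intracellular volumes exist only where they
have dynamical meaning: kidney (0.24 L, prorenin pool) and liver
(study-specific 1.35–1.57 L, site of AGT secretion and drug conversion).

## Steady-state closure

The intracellular AGT concentration is not an observable of the model's
data basis, yet hepatic AGT secretion must balance plasma losses.  At
assembly time the package therefore computes two zero-order synthesis
fluxes once and freezes them:

* AGT: synthesis = plasma degradation + renin-mediated conversion,
  both evaluated at the reference venous concentrations; the reference
  intracellular concentration follows as `flux / k_Secretion`.
* prorenin: synthesis = activation (at reference renal Ang2) + secretion,
  evaluated at the printed renal intracellular reference (1.1e-4 µmol/L).

This anchors the drug-free model to the published venous steady state
while leaving the intracellular pools dynamic during inhibition (falling
renal Ang2 accelerates prorenin activation, draining the pool).

## Aldosterone drive

The published cascade links aldosterone synthesis to the AT1–Ang2
complex without naming the organ whose receptor pool drives the adrenal;
adrenals are absent from the expression table.  Default here: the
plasma-volume-weighted whole-body mean complex concentration drives
synthesis, and aldosterone is secreted into the venous pool (adrenal
venous drainage).  A `complex_source="kidney"` switch restricts the
drive to the kidney's local complex.

## Drug model choices

* Dose handling: mg → µmol via MW 376.5 (Ena) / 348.4 (Enaat); the
  maleate-salt correction is ignored (study doses are reported as Ena mg).
* Oral absorption: first-order depot (`ka`, default 0.03 min⁻¹) charged
  with `f_abs · dose` (default 0.6); the remainder is never absorbed.
  Both are exposed in configuration and are the quantities identified by
  the random-search workflow rather than asserted.
* Only the liver carries an intracellular drug compartment (needed for
  hydrolysis and hepatic clearance), exchanging with liver plasma by a
  perfusion-limited permeability term with equilibrium ratio `K_org`
  (default 1.0 — both compounds are hydrophilic, log P 0.07 / −0.74).
  Other organs are plasma-only for the drugs.
* Hepatic clearance of Ena (354 ml/min) acts as a linear intrinsic
  clearance on liver intracellular Ena, in parallel with hydrolysis.
* Renal clearance uses the study-specific per-kg values; the
  compound-level whole-body clearances in the drug file are metadata.
* Protein binding percentages are stored but rates act on total plasma
  concentrations.

## Numerics

* Stiff integration: `scipy.integrate.solve_ivp` BDF, rtol 1e-8, atol
  1e-12 µmol, with a numerically probed Jacobian sparsity pattern
  (half-lives of 0.72–12.87 min against multi-day PK horizons make the
  system stiff).  Halving the tolerances moves reported venous
  concentrations by < 0.1% (tested).
* Dose events restart the integrator with an exact depot increment — no
  smoothing, bit-deterministic for identical inputs (trajectory content
  hash tested).
* Steady state: long-horizon integration (≥ 5000 min, 10× the longest
  half-life chain) followed by a Newton (hybr) root polish on the
  non-accumulator states, accepted only if max |dA/dt| / max(A, ε)
  < 1e-9 min⁻¹.  Inside identification loops the order is reversed
  (warm-started root solve, integration as fallback).
* Negative-state policy: the solver runs unconstrained; trajectories are
  checked post hoc against a −1e-12 µmol floor rather than clipped, so a
  modelling error cannot hide behind clipping.
* The absorption-fitting stage integrates a reduced 54-state drug-only
  system (gut, plasma amounts, liver pools, ACE complexes) at relaxed
  tolerances (rtol 1e-6/atol 1e-10; the random search itself uses
  rtol 1e-5-equivalent accuracy far below the 15% data noise).  Its
  equivalence to the full system is pinned by a test.

## Identification

* Objective: RMS of relative residuals — targets span 0.60 down to
  3.62e-7 µmol/L, so absolute residuals would see only angiotensinogen.
  An absolute mode exists for targets containing zeros.
* Cascade identification: the 20 parameters marked `optimized` in the
  parameter file are free (the Ang2 half-life is literature-fixed),
  searched in log10 space within ×0.01–×100 of their initial values,
  Nelder–Mead (scipy) with a custom initial simplex of 0.5 log10 units
  per coordinate and restart-at-best with a shrinking step.  The wide
  initial simplex matters: the aldosterone branch must travel ~3 orders
  of magnitude, which the conventional 5% initial simplex cannot do
  within budget.  Budget 3000 evaluations (~3 min on one CPU); the fit
  reaches relative RMS < 1e-3 against the six venous steady-state
  targets.
* Parameter non-uniqueness is inherent (20 parameters, 6 targets); the
  workflow reproduces the published identification strategy, not a claim
  of identifiability.  Single-parameter recovery is verified for
  parameters with direct steady-state leverage (half-lives, renin kcat).
  Note that `AGT.k_secretion` is structurally non-identifiable from
  steady-state concentrations here because the AGT closure recomputes the
  intracellular reference from it.
* Drug absorption: uniform/log-uniform random search (2000 seeded draws)
  over ka ∈ [0.005, 0.1] min⁻¹ (log) and f_abs ∈ [0.2, 1.0] (linear),
  deterministic per seed.

## Synthetic data generator

`generate_fixtures` produces: virtual subjects sampled uniformly within
the ranges spanned by the six published study populations; oral-Ena
concentration-time curves at clinical-like sampling times (0.25–48 h)
with 15% multiplicative lognormal noise and an assay-like lower limit of
quantification (default 1e-3 µmol/L) below which samples are dropped;
and steady-state target tables with optional noise.  It emulates design
and noise level, not inter-individual PK variability, assay bias,
food-effect kinetics or dropout — so passing recovery tests demonstrates
estimator correctness under the stated noise model, not performance on
real clinical data.

## Problem sizes used in the shipped checks

Steady-state construction solves the 180-state system (17 compartments ×
8 plasma species + 2 complex fields + 10 scalar pools); the acceptance
workflow runs the 20-parameter simplex fit at a 3000-evaluation budget;
the absorption recovery uses one synthetic curve (7 quantifiable Ena +
15 Enaat samples) and 2000 random draws; dosed scenarios integrate 3000
min (dose at t = 1500 min) on a 5–25 min output grid.

## Known limitations

* Absolute per-organ volumes/flows are package-chosen; organ-level
  concentration gradients are therefore indicative only, and the
  identified rate constants are conditional on this physiology.
* No blood-pressure or heart-rate endpoint; no Ang(1–7)/ACE2 or chymase
  arms; no tissue (non-circulating) RAAS.
* No mechanistic intestinal transporter model (first-order absorption
  stands in for carrier-mediated uptake); no biliary excretion; no
  Enaat → Ena back-conversion.
* AT1-complex internalisation is not modelled; per-organ receptor totals
  are strictly conserved.
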