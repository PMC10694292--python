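# Methods

## Model structure and assumptions

Each drug family (parent plus quantified metabolites) is an independent
compartmental system; drug–drug interactions within the cocktail are
not modelled, so the six families can be simulated and fitted
separately.  The topology is a deliberate reduction of a whole-body
PBPK model to five physical compartments — plasma, liver blood,
hepatocyte, kidney, rest-of-body — plus three cumulative sinks (urine,
bile, unknown metabolites).  This is the smallest structure that can
express every mechanism the analysis distinguishes: sinusoidal uptake
and export, canalicular export, hepatic phase-I/phase-II metabolism,
and renal filtration.  Kidney and rest-of-body are flow-limited with
tissue:plasma partition coefficients; liver blood is a well-stirred
sub-compartment exchanging with plasma at hepatic blood flow and with
the hepatocyte through passive diffusion and/or carriers.

Units are fixed package-wide: nmol, L, nmol/L, min, L/min; transporter
capacities in nmol/min with affinities in nmol/L.  All clearance and
transport rates act on unbound concentration (constant fraction
unbound; no binding kinetics).  Transport Km is fixed at 1000 nmol/L
(1 µmol/L) everywhere and is never estimated — at cocktail doses the
carriers therefore operate partly saturated, which is intended; the
linearity property holds only in the low-dose limit and is asserted
both positively (tracer dose) and negatively (cocktail dose) in the
tests.

Glucuronides carry zero passive membrane permeability, so carriers are
their only exits from the hepatocyte: Abcc3/Abcc4 across the sinusoidal
membrane into blood, Abcc2 across the canalicular membrane into bile.
Without this constraint the biliary (H2) and sinusoidal-export (H3)
hypotheses would not be mechanistically distinct.

## Parameters

Mouse physiology defaults (25 g animal, linear scaling in body weight):
plasma 1.0 mL, liver blood 0.3 mL, hepatocyte 1.2 mL, kidney 0.4 mL,
rest-of-body 19 mL; blood flows liver 1.8, kidney 1.3, rest-of-body
5.0 mL/min; GFR 0.25 mL/min; bile flow 2.5 µL/min.  These are standard
rodent reference values shipped as an editable configuration.

Drug-specific kinetic parameters are placeholders on literature scales,
not measured constants; they were chosen once so that the shipped
models express the qualitative disposition structure the analysis is
about, and the fitting machinery treats them as the estimable unknowns
they are in practice:

* CYP substrates have moderate hepatic extraction (intrinsic clearance
  within an order of magnitude of liver blood flow), so reducing CYP
  activity to 11% visibly slows parent clearance;
* glucuronidation is a minor route of the phase-I metabolite's hepatic
  fate (~1% for 1-hydroxymidazolam against a dominant
  unknown-metabolite clearance), leaving the UGT hypothesis headroom of
  more than an order of magnitude, consistent with fitted UGT folds in
  the tens being admissible;
* glucuronide export is mostly canalicular at baseline (10% sinusoidal
  share, total carrier capacity 0.8 nmol/min, hepatocyte residence
  half-time of a few minutes), so a biliary-clearance reduction must
  slow glucuronide kinetics into the sampling window to mimic the data
  — the property that lets 2-h bile collections discriminate H2 from
  H3;
* torsemide and pravastatin enter hepatocytes only through Slco1b2
  (zero passive permeability), making their disposition sensitive to
  uptake-carrier downregulation; talinolol is exported into bile by
  Abcb1a.

Cocktail doses are 5/2/2/20/1/2 mg/kg (caffeine, codeine, midazolam,
pravastatin, talinolol, torsemide), converted to nmol with standard
molecular weights and administered as simultaneous i.v. boluses at
t = 0.

## Disease scenario and hypotheses

`apply_cirrhosis` multiplies every CYP-labelled enzymatic clearance and
every unknown-metabolite clearance by `cyp_fraction` (default 0.11, the
measured residual area of CYP-expressing hepatocytes used as a lumped
surrogate for pericentral enzyme loss); UGT processes are deliberately
untouched, so the reference cirrhosis simulation under-predicts
circulating glucuronides — the discrepancy the hypotheses compete to
explain.  Transporter capacities are scaled by per-gene multipliers
with recorded provenance: derived multipliers use 2^log2FC for genes
passing the mouse differential-expression threshold (non-significant
genes default to 1.0 — a robustness gate this package adds), while the
shipped scenario marks Slco1b2 (0.5) and Abcb1a (2.0) as fixed
configuration values.  A hypothesis is one fold change θ > 0 applied to
its target processes: H1 → Ugt steps, H2 → Abcc2 canalicular export,
H3 → Abcc3/Abcc4 sinusoidal export, optionally restricted to a single
glucuronide.  Both transformations are pure functions and commute on
disjoint targets; the null settings (fraction 1, empty scaling, θ = 1)
reproduce the reference simulation bit-exactly.

## Numerics

The state equations assemble into one first-order rate matrix plus a
short list of Michaelis–Menten terms; the Jacobian is analytic.
Integration uses a stiff-capable solver (LSODA) at rel 1e-8 / abs 1e-10
nmol, restarting at each bolus time; outputs at a dose time are
post-bolus.  State layout is species-major and documented; solver
wiggle below zero within tolerance is clamped, anything beyond raises.
Determinism is part of the contract: identical inputs produce identical
output bytes.  Parent-equivalent molar balance (every metabolite counts
as one mole of parent) holds to rel 1e-6 at all output times and is
enforced in the tests.

## Estimation

The objective is Σ w·(log(pred+ε) − log(obs+ε))² with ε = LOQ/2 per
readout kind (plasma 0.5 nmol/L, urine/bile 0.05 nmol); observations
flagged below LOQ are replaced by LOQ/2 and down-weighted ×0.5.  Log
residuals were chosen because concentrations span orders of magnitude
across analytes and times.  Optimisation is bounded least squares in
log-parameter space (default bounds 10^±3 around the start) with a
seeded multi-start: the first start is the supplied value, further
starts are rows of a single 64-row Latin-hypercube sample of the log
bounds, so increasing the start count never discards earlier starts and
the best objective is monotone in the number of starts.

The joint fit shares reference parameters across arms: the control arm
uses the reference model, the cirrhosis arm the scenario-transformed
model with θ free; the objective is the sum of both arms plus optional
auxiliary terms.  The microsomal glucuronidation-activity ratio enters
as such a term: each hypothesis predicts θ for its own assay and 1.0
for the others, confronting the PK fit with non-PK evidence exactly
where the hypotheses make distinct predictions outside the plasma
window.

## Synthetic cohorts

The generator emulates the in-vivo design: i.v. bolus at t = 0, plasma
at 15/30/60/120 min for every analyte, one cumulative 24-h urine value
and one cumulative 2-h bile value per animal (bile only for species
with a canalicular route).  Measurement error is multiplicative
lognormal with CV 20% by default (typical bioanalytical precision);
inter-animal variability applies independent lognormal multipliers
(CV 30%) to each hepatic process parameter per subject.  Default group
size is five animals per arm.  The generator does not emulate: the
disease induction history, body-weight differences between groups,
correlated inter-parameter variability, time-varying physiology, drug
interactions within the cocktail, or assay-specific error structure
beyond the single CV — so passing recovery tests demonstrate that the
estimation machinery works under the assumed error model, not that real
cirrhotic-mouse data would be this well behaved.

## Problem sizes and reported quantities

The recovery experiment uses 20 seeded replicate cohorts (5+5 animals,
true H3 fold 10) with three optimisation starts per fit; the
discrimination experiment 20 replicates with two starts per hypothesis;
the plasma-only identifiability spread 3 replicates.  These sizes give
stable medians and win counts while keeping a full analysis run in the
minutes range on a single core.  The acceptance script recomputes every
reported number at run time from the given seed; nothing is stored.

## Limitations

* Topology and all drug-specific constants are reduced placeholders;
  absolute simulated concentrations are not predictions for real mice.
* No oral absorption, enterohepatic recirculation, protein-binding
  kinetics, or liver zonation; the 11% factor is a lumped surrogate.
* Renal handling is filtration only (no secretion or reabsorption).
* The objective function and optimiser settings are package
  conventions; fitted fold changes are comparative quantities, not
  physiological measurements.
* Differential-expression computation is upstream: the transcriptome
  module consumes result tables and never downloads data.
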