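# Methods

This note documents the models, the synthetic-study generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Pharmacokinetic model

Linear mammillary two-compartment system with a first-order absorption depot
(intraperitoneal injection site) and first-order elimination from the
central compartment.  Internal units are hours, micrograms, and mL
throughout; clearances quoted in mL/day are converted on ingestion and AUC
is reported in µg·day/mL (the convention of preclinical study reports).

Two evaluation paths exist and are cross-checked against each other and
against an independent high-accuracy integration in the tests:

* an ODE path (`simulate_pk_profile`, DOP853, rtol 1e-10 / atol 1e-13,
  integration restarted at every dose event so depot discontinuities are
  exact), which also exposes the full amount trajectory for mass-balance
  checks; and
* the tri-exponential closed form (`closed_form_concentration`), the
  eigen-solution over the rates (α, β, ka).  Multiple doses are handled by
  superposition, valid because the system is linear.

Degenerate rate coincidences: the one-compartment case ka = ke uses the
exact confluent limit (F·D/Vc)·ka·t·e^(−ka·t), entered when
|ka − ke| < 1e-10·ka.  A two-compartment coincidence (measure-zero in
practice) is resolved by a 1e-7 relative rate split, or raised as an error
when `degenerate="raise"`.

**Default parameters** (generator truth and fit initialization): ka = 0.54
1/h, Vc = 2.61 mL, CL = 3.11 mL/day — the reported mouse estimates.  Q =
0.04 mL/h and Vp = 2.6 mL are *assumed* (unreported anywhere) and freely
overridable; F is fixed at 1 (intraperitoneal absorption treated as complete
first-order input; no bioavailability was reported).  "Twice weekly" is
encoded as uniform 84-h spacing by default, with a 72/96-h alternating
option.

**Fitting** is pooled (naive) nonlinear least squares on log concentrations
— equivalent to a proportional error model, appropriate for data spanning
several decades — shared across dose groups, with 5 multi-start
initializations log-uniformly perturbed within 3× of the user's initial
values.  Observations below the LLOQ (default 0.05 µg/mL) are flagged and
excluded from the objective.  Standard errors come from the Jacobian-based
covariance at the optimum (residual-variance scaled), delta-transformed from
the log scale.

**Identifiability at the study design.**  The sampling schedule (days 1, 2,
3, 4, 7 and 14 after the first dose) contains no draw inside the absorption
phase (half-life ~1.3 h at ka = 0.54 1/h) or the early distribution phase.
Profile analysis shows the objective is nearly flat in ka above ~0.3 1/h:
ka enters the post-absorption curve only through the scale factor
ka/(ka − ke), which is almost collinear with 1/Vc.  Consequently the default
fit estimates only ka, Vc and CL and holds the assumed Q and Vp fixed;
estimating all five (available via `vary`) makes the problem
ridge-degenerate and ka estimates diverge under noise.  Even in the
three-parameter fit, ka is the least certain parameter (median relative
error ≈ 25% at 20% concentration CV) — a property of the design, not of the
optimizer.

## Receptor occupancy

The assay competes PE-labeled antibody (fixed at 6.8 nM, equal to 1 µg/mL
via the antibody's molar bridge — a single constant used everywhere) against
unlabeled antibody for surface EGFR, with a non-competing labeled anti-EGFR
antibody as the total-receptor denominator.  The primary model is
no-depletion equilibrium with equal affinities: labeled-bound fraction
L/(L + U + Kd).  A depletion-aware fixed-point equilibrium solver exists in
the test suite as an independent oracle only; at the assay's receptor
densities the two agree to < 1e-4.

The standard curve normalizes each replicate-averaged ratio to the
zero-competitor anchor, S = 100·(1 − r/r₀), and interpolates with a
shape-preserving monotone (PCHIP) interpolant, guaranteeing invertibility.
Saturation dips up to 10 percentage points (the scale of assay noise after
replicate averaging) are flattened; larger inversions are rejected with
diagnostics.  Out-of-span ratios are clamped with a warning.

Kd fitting supports both data routes, since which one produced the reported
estimate is not stated:

* competition series: ratio = r₀·L/(L + U + Kd) fitted on log ratios,
  jointly estimating Kd and the signal scale r₀.  Fitting with L known
  recovers the true Kd rather than the competition-shifted apparent constant
  Kd + L — the reason a plain hyperbola must *not* be fitted to competition
  data.
* saturation-vs-concentration pairs: S = Smax·C/(Kd + C), Smax fixed at
  100% by default (the assay is normalized to 100%) and optionally
  estimated.

Kd is treated as nM (the units of the reported 0.922 value are unstated) and
also reported in µg/mL through the molar bridge.  Designs whose
concentrations all sit far above the fitted Kd are flagged non-identifiable.

## Tumor growth inhibition

Simeoni-type structure: per-capita switching growth rate
g(w)/w = λ0/[1 + (λ0·w/λ1)^ψ]^(1/ψ) applied to the proliferating
compartment, drug-induced transfer at rate K(C) = Emax·C/(EC50 + C) into a
chain of `n_transit` damage compartments (default 3) traversed at rate k1,
and total burden w = Σxᵢ by construction.  λ0 (1/h, exponential phase) and
λ1 (mm³/h, linear phase) are stored separately and never conflated: the
eradication criterion CT = λ0·EC50/(Emax − λ0) is only dimensionally
coherent against the first-order rate.  λ1 = ∞ selects pure-exponential
growth; the switch computation is done in a scale-stable form so large ψ
(default 20) cannot overflow.

The driving exposure is central serum concentration; within each inter-dose
segment the superposed closed form collapses onto the model's three
exponentials, which makes simulation inside fitting loops cheap while
agreeing with a reference integration to ~1e-7 where the burden is
physically meaningful (> 1e-3 of baseline).  Integration is LSODA at rtol
1e-8 / atol 1e-9, restarted at dose times.

**Fitting** is sequential on group means of log volumes floored at 1 mm³
(eradicated tumors are recorded as 0): growth parameters (λ0, λ1, w0) on
the control group first, then kill parameters (Emax, EC50, k1) on the
treated groups with growth and PK fixed.  ψ and the transit count are held
fixed (neither is estimable from volume curves at this design).

**Kill-parameter defaults.**  The reported kill values (Emax 8.97 1/h, EC50
0.81 µg/mL) are retained as `printed_tgi_params()` and exercised in
simulation tests, but they cannot serve as generator truth for recovery
work: a kill rate ~2000× any plausible tumor growth rate, saturated at
every study dose, empties the proliferating compartment within minutes of
the first dose at *all* doses, so the simulated volume curves are identical
across dose groups and carry no information about Emax or EC50 — and a
model with those values also contradicts the study's observed outcome, in
which the two lowest dose groups kept growing.  The default truth
(`study_consistent_tgi_params()`) therefore uses kill parameters
commensurate with growth — λ0 = 0.005 1/h (doubling ≈ 5.8 days), λ1 = 6
mm³/h (switch near 1200 mm³), Emax = 0.011 1/h, EC50 = 5 µg/mL, k1 = 0.03
1/h, w0 = 300 mm³ — chosen once, by analysis, to reproduce the study's
qualitative dose-response: partial inhibition at 5 and 20 µg, regression
and near-eradication at 200 and 500 µg.  The implied tumor-static
concentration is ≈ 4.2 µg/mL, between the sustained exposures of the
partially inhibited and eradicated dose bands.

The threshold-dichotomy validation (constant exposure 5% above CT clears
the tumor to < 0.1% of baseline; 5% below sustains growth) is run in the
exponential configuration (λ1 = ∞): CT is an exponential-phase criterion,
and with finite λ1 a sub-threshold tumor plateaus at w* = λ1/K instead of
growing indefinitely.  Simulation horizons are set analytically from the
net kill/growth margin so the check is well-conditioned for random
parameter draws.

## Synthetic-study generator

Emulates the study layout: five tumor groups (vehicle control plus 5, 20,
200, 500 µg twice weekly, n = 10), PK sampling at days 1, 2, 3, 4, 7, 14
(n = 5 per time point; 20/200/500 µg groups), tumor volumes
(length × width × height, mm³) measured twice weekly from ~300 mm³
baselines through day 52 with dosing through day 50, the six-concentration
in vitro competition series (0, 0.21, 0.63, 1.83, 5.64, 17 nM vs 6.8 nM
labeled; 3 replicates), and in vivo saturation sampling at days 1, 3, 4, 7.

Noise models are standard pharmacometric choices: mean-one lognormal
multiplicative noise for concentrations (default 20% CV) and assay ratios
(5% CV); additive-plus-proportional truncated normal noise for tumor
volumes (15% CV + 5 mm³); per-animal baselines lognormal around 300 mm³
with 20% CV.  One global seed spawns independent deterministic sub-streams
per dataset, so each table is reproducible in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: tumor drug penetration gradients and interstitial
pressure (serum concentration stands in for concentration at the tumor),
receptor internalization and turnover, target-mediated clearance
(negligible here because the antibody does not bind the mouse receptor),
inter-animal PK variability (observations share one PK truth), drop-out or
euthanasia rules, and measurement-schedule irregularities.  The in vivo
saturation readouts are derived from serum PK through the equilibrium
hyperbola, so they saturate much faster than tumor-dissociation assays do
in practice.

## Pipeline and reproducibility

The pipeline runs PK → occupancy → tumor fitting sequentially (a joint fit
is out of scope), feeding the fitted PK into the tumor stage, and captures
stage failures as explicit report entries rather than aborting.  Configs
and reports are pydantic-validated JSON; reports carry a config hash, the
seed, and the package version.  Monte-Carlo problem sizes used by the test
suite, chosen for a laptop-scale single-CPU run: 50 seeds (20% CV) and 100
seeds (5% CV) for PK recovery, 100 seeds for Kd interval calibration, 12
seeds for tumor kill-parameter recovery at 15% volume noise (medians are
stable at this size), 10 random parameter sets for the threshold dichotomy.

## Known limitations

* The first-dose AUC window is exposed as a parameter rather than fixed:
  a single-dose AUC∞ = F·D/CL at the default clearance is not reconcilable
  with every reported exposure figure, and the integration window behind
  those figures is unstated.
* Pooled fitting only; no mixed-effects (population) estimation.
* Censored concentrations are excluded, not imputed — the simplest
  defensible LLOQ rule.
* ka is weakly identified at the default sampling design (see above); its
  standard error honestly reflects that only when Q and Vp are held fixed.
* Group-mean tumor fitting is the default; individual-animal fitting is
  possible by passing per-animal tables but is not exercised by the tests.
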