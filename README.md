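# xenopkpd

PK/PD modeling of monoclonal-antibody efficacy studies in tumor
xenograft-bearing mice: pharmacokinetics of twice-weekly intraperitoneal
dosing, EGFR receptor occupancy from a ratiometric competitive-binding assay,
and tumor growth inhibition with a saturating kill term, including the
tumor-static ("eradication") concentration.  The package is aimed at
pharmacometricians and preclinical modelers who want the whole chain —
simulate a study, fit each stage, and derive the exposure threshold for tumor
regression — as tested, reusable code.  A synthetic-study generator emulating
an A431 epidermoid-carcinoma xenograft experiment makes every stage testable
without animal data.

## Models

**Pharmacokinetics.** Open two-compartment model with first-order absorption
from the injection site and first-order elimination from the central
compartment:

    dA_d/dt = -ka·A_d
    dA_c/dt =  ka·A_d - (CL/Vc)·A_c - (Q/Vc)·A_c + (Q/Vp)·A_p
    dA_p/dt =  (Q/Vc)·A_c - (Q/Vp)·A_p,        C = A_c/Vc

Both an ODE path and the tri-exponential closed form (eigen-solution) are
provided and cross-checked; multiple doses superpose and exposure metrics
(C_max, AUC) scale exactly with dose.  Q = 0 reduces the model exactly to the
one-compartment Bateman function.

**Receptor occupancy.** PE-labeled antibody at fixed L competes with
unlabeled antibody at U for surface EGFR; under no-depletion equilibrium the
labeled-bound fraction is L/(L + U + K_d).  A zero-competitor-anchored
standard curve maps signal ratios to percent saturation, and saturation
follows the hyperbolic E_max (Langmuir) model S(C) = S_max·C/(K_d + C).

**Tumor growth inhibition.** Simeoni-type model: exponential-then-linear
unperturbed growth (rates λ0 [1/h] and λ1 [mm³/h], sharp switch ψ), with a
drug-driven kill term K(C) = E_max·C/(EC50 + C) moving proliferating cells
through a chain of transit (damage) compartments at rate k1 before loss.
The tumor-static concentration — steady exposure at which kill exactly
balances exponential-phase growth — is

    CT = λ0·EC50 / (E_max - λ0),     finite only when E_max > λ0.

## Worked example

Run the full pipeline (synthesize a study at the default design, fit PK →
occupancy → tumor model, derive the threshold):

```sh
xenopkpd run --seed 1 --out report.json
```

The report (abridged; estimate ± SE) from that exact command:

```
pk         ka 0.565 ± 0.199 1/h, Vc 2.418 ± 0.178 mL, CL 0.1281 mL/h (3.07 mL/day)
occupancy  Kd 1.258 ± 0.473 nM
tgi        λ0 0.0047 1/h, λ1 5.80 mm³/h, Emax 0.0104 1/h, EC50 4.70 µg/mL, k1 0.044 1/h
eradication concentration: 3.87 µg/mL
```

The generating truth was ka 0.54 1/h, Vc 2.61 mL, CL 3.11 mL/day, Kd
0.922 nM, λ0 0.005 1/h, λ1 6 mm³/h, Emax 0.011 1/h, EC50 5 µg/mL: each
estimate recovers its generating value within roughly its standard error at
the study's noise levels (20% CV serum concentrations, 15% CV tumor volumes,
5% CV assay ratios).  The dose-proportionality table in the same report
shows modeled first-dose C_max and AUC scaling exactly linearly across the
20/200/500 µg groups — the defining property of linear PK, e.g. an AUC of
30.2 µg·day/mL at 20 µg implies exactly 755 µg·day/mL at 500 µg.

Other entry points: `xenopkpd simulate` (write a synthetic study bundle),
`fit-pk` / `fit-occupancy` / `fit-tgi` (single stages), `eradication`
(threshold from configured parameters), `recover` (Monte-Carlo
parameter-recovery experiment).  All accept `--config` (JSON; schema in
`docs/pipeline_config.schema.json`), `--seed`, `--out`.  The same
functionality is available as a library (`xenopkpd.pk`, `.occupancy`,
`.tgi`, `.synthetic`, `.pipeline`).

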