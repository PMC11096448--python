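# Methods

## Scope and model structure

`codeine_pbpk` simulates the disposition of oral or intravenous codeine and
its CYP2D6-formed metabolite morphine in a virtual adult. The model is a
whole-body PBPK system with 18 compartments: lung, liver, kidney, gut,
stomach, spleen, pancreas, muscle, adipose, brain, heart, skin, bone,
gonads, a lumped rest-of-body tissue, and arterial, venous and portal
blood. All tissues are perfusion-limited:

    dA_i/dt = Q_i (C_in − C_out,i),   C_out,i = (A_i / V_i) · (B:P) / Kp_i

with amounts in µmol, flows in L/min and concentrations in µM internally;
plasma concentrations are reported as venous plasma in ng/mL (µM × MW).
Venous blood collects all systemic organs, perfuses the lung and returns
as arterial blood; gut, stomach, spleen and pancreas drain into the portal
vein, which joins the hepatic artery at the liver. Both analytes share the
physiology; they differ in partitioning, binding and clearance. Morphine
formation is stoichiometrically linked 1:1 molar to the codeine CYP2D6
flux. Both compounds are small and moderately lipophilic, so no
permeability-limited tissue model is used.

## Physiology

The paper-trail for this class of model runs through commercial platforms
whose virtual populations are not printable, so the package ships its own
reference physiology as auditable YAML data: a canonical organ table
(volumes and blood-flow fractions for a 73-kg adult male, compiled from
standard reference-man tables) plus per-reference anthropometry files. Four
ethnic references are provided (European 73 kg, Asian 60 kg,
African-American 80 kg, White-American 78 kg). Only anthropometry differs
between them — organ volumes scale isometrically with body weight, cardiac
output and GFR allometrically with exponent 0.75 — and enzyme abundances
are deliberately identical across ethnic references. Female references
apply a body-weight ratio of 0.82 to the male file. Flow fractions are
renormalised in code so systemic flows always sum to cardiac output.

Virtual populations perturb the reference by independent log-normal factors
with unit median: organ volumes CV 10%, blood flows CV 15% (renormalised to
cardiac output afterwards), enzyme abundances CV 35%, typical settings for
adult PBPK population simulation. Body weight of a sampled individual
tracks its total sampled organ volume, which keeps the anatomical
invariants (organs fit into the body; flows balance) true by construction.
Zero variability returns the reference exactly; all sampling is driven by a
single integer seed.

## Partition coefficients and permeability

Tissue:plasma partition coefficients use the Rodgers–Rowland mechanistic
scheme for ionisable compounds. The unbound tissue:plasma ratio sums:

* extracellular water (fraction f_EW);
* intracellular water weighted by the ratio of ionisation factors
  `Y(pH_iw)/Y(pH_p)`, where `Y = 1 + 10^(pKa_b − pH) + 10^(pH − pKa_a)`
  keeps only the terms present for the compound class (codeine: monoprotic
  base; morphine: ampholyte with both terms; intracellular pH 7.0, plasma
  7.4);
* neutral lipid and phospholipid, `P·f_NL + (0.3 P + 0.7)·f_NP` with
  `P = 10^logP`, available to the neutral species only;
* electrostatic association of the cation with acidic phospholipids,
  `Ka_AP · AP · 10^(pKa_b − pH_iw)`, with `Ka_AP` solved from the measured
  blood:plasma ratio via the blood-cell composition
  (`Kpu_BC = (Hct − 1 + B:P)/(Hct · fup)`); if the measured B:P leaves no
  residual affinity the term is dropped.

The total is normalised by the plasma phase (water + neutral lipid terms),
a small refinement that makes the coefficient exactly 1 for a hypothetical
tissue with plasma's own composition, and multiplied by fup to give Kp on a
total-plasma basis. Tissue compositions (water sub-fractions, lipids,
acidic phospholipid content, intracellular pH) are compiled from the
standard published composition tables used with this method; stomach,
gonads and rest-of-body reuse gut-like generic values.

Cellular permeability uses the package's own lipophilicity/size
correlation, `log10 P[cm/min] = 2.41 + 0.47·logP − 2.0·log10(MW)`,
anchored so a lipophilic opiate (logP 2.6, MW ≈ 300) lands in the
high-permeability class (≈8×10⁻⁴ cm/s) and a hydrophilic one (logP 0.77)
in the moderate class (≈1×10⁻⁴ cm/s), consistent with Caco-2/PAMPA ranges.
It feeds the intestinal absorption rate constant only.

## Clearance: decomposing the specific clearance

The compound files list, for codeine, both a literature total hepatic
plasma clearance (20.32 mL/min/kg) and a platform-style *specific
clearance* (1.88 min⁻¹) derived from it, alongside three enzyme pathways
with their own Km and kcat/Vmax. Applying all of these as independent
processes would double-count hepatic elimination. The package's resolution:
the specific clearance is the authoritative **total hepatic intrinsic
clearance anchor** (first-order on unbound liver concentration, scaled by
liver volume), and the enzyme pathways are its **decomposition**, weighted
by their kinetic ratios `w_p = kcat_p/Km_p` or `Vmax_p/Km_p` under a common
reference enzyme amount `E_ref = CLint_total / Σ w_p`. With the shipped
kinetics this yields a codeine split of ≈5.5% CYP2D6 / ≈9% CYP3A4 / ≈85%
UGT2B7 — matching the known disposition of codeine (5–10% O-demethylation,
5–15% N-demethylation, 70–80% glucuronidation), which is the main argument
for this reading. CL_met stays in the file as provenance metadata only.
Morphine's specific clearance (5.14 min⁻¹) is carried entirely by its
UGT2B7 pathway. Pathway rates are Michaelis–Menten in the unbound liver
concentration `Cu = fup · A_liver/(V_liver · Kp_liver)` (the well-stirred
choice; whether the original platform drove metabolism with unbound plasma
or unbound intracellular concentration is not documented, and at
therapeutic doses the two differ only through saturation at very large
doses). Renal clearance applies the per-kg plasma values (codeine 5,
morphine 6.5 mL/min/kg) to kidney outflow plasma.

A single calibrated scale factor multiplies the CYP2D6 capacity: it is
fitted once so that the Asian extensive-metaboliser reference (activity
score 1.5) after a single 30 mg codeine tablet reproduces the reference
morphine exposure of 9.07 ng·h/mL, then frozen in the constants file
(value 2.433). Only the product kcat × enzyme amount is identifiable from
plasma data, so the kcat values act as ratios and this one scale sets the
absolute morphine yield. `calibrate_cyp2d6_scale()` re-derives it in a few
secant iterations (exposure is nearly proportional to the scale).

## CYP2D6 activity-score phenotyping

The packaged table maps activity scores to turnover frequencies:
AS 0 (PM) → 0.03 min⁻¹, 0.5/0.75/1 (IM) → 0.40/0.6/0.8, 1.25–2 (EM) →
0.96/1.6/1.87/2.16, 2.5/3 (UM) → 2.4/2.8 min⁻¹, with AS 1.5 (1.6 min⁻¹) as
the 100% reference. The PM value is deliberately a small positive number
rather than zero: clinical data show residual morphine exposure in PMs.
Scores between rows interpolate linearly; AS 2.75 (the UM representative
used in dose simulations) → 2.6 min⁻¹. Two data quirks are documented
rather than hidden: (i) the AS 1.25 row's printed relative turnover (65%)
is inconsistent with its own kcat (0.96/1.6 = 60%) — the kcat column is
authoritative; (ii) a strictly linear formation-limited model bounds the
morphine-exposure increase of a UM with kcat 2.6 min⁻¹ at +62.5% over EM
(the bound is `kcat ratio − 1`, approached only as the CYP2D6 share of
codeine clearance vanishes), so published UM increases above that bound
cannot be reproduced under table-interpolated turnover — the package
reports what the mechanism yields (≈ +52%).

## Oral absorption

Formulation release follows a Weibull curve parameterised directly by the
50%-dissolution time, `f(t) = 1 − 2^(−((t − lag)/t50)^shape)`, so
`f(lag + t50) = 0.5` exactly (equivalently, scale = t50/(ln 2)^(1/shape) in
the exponential form). Shipped parameters: capsule t50 5 min shape 1.0,
tablet 5 min / 0.92, sustained-release 100 min / 1.2; solutions and
immediate-release tablets count as dissolved at administration. Dissolved
drug empties from the stomach (first-order, half-time 15 min) into a
6-segment small-intestine chain (total transit 3.3 h) and is absorbed from
each segment at `ka = 2·P_cell/r` with effective radius 1.25 cm; drug
leaving the last segment is lost to a faecal sink. These transit constants
are standard adult values; they are the package's own minimal
reconstruction since no transit detail is published for this model.
Solubility limitation is not modelled — at therapeutic codeine doses
(≤ 80 mg in ≥ 250 mL fluid, solubility 0.577 mg/mL) it never engages; the
1500 mg poor-metaboliser scenario exceeds it and logs a warning instead.
Multiple doses repeat at the dosing interval; intravenous boluses enter the
venous pool as state jumps, infusions as zero-order input (default 30 min).

## Numerics

The coupled system (2 × 18 organ states, 7 gut states, cumulative
bookkeeping states; 51 in total) is integrated with LSODA at rtol 1e-8 /
atol 1e-10 µmol (rtol 1e-6 / atol 1e-8 inside Monte-Carlo loops, where
thousands of simulations run). Integration restarts at every dose event;
output is a 0.02 h grid by default (callers can refine it, e.g. around the
intravenous mixing spike). The Weibull release rate for shape < 1 has an
integrable singularity at the dose instant; the rate is evaluated from the
event time onwards and the solver's adaptive first step handles it. Mass
balance (administered = undissolved + luminal + absorbed-in-body + faecal +
urinary + metabolised, and formed = accounted for morphine) is checked to
≤ 0.1% at every output time in the test suite and typically holds to 1e-8.
Concentrations are clipped at zero on output; Michaelis–Menten rates clamp
negative transients. NCA uses linear-up/log-down trapezoids; the terminal
slope takes the candidate window (last k ≥ 3 positive points strictly after
Tmax) with the best adjusted R², mirroring common NCA software defaults;
profiles without an estimable negative slope report the extrapolated
quantities as absent with a warning, and an all-zero profile returns zeros.

Fold-error statistics use MFE = predicted/observed, GMFE =
10^(mean |log10 MFE|), and the conventional acceptance rule that mean MFE
and GMFE lie within [0.5, 2] per parameter. Monte-Carlo identification is a
pure random search (log-uniform for positive scale parameters), scored by
the sum of squared residuals on log concentrations with equal weights — the
log scale matches the fold-error evaluation philosophy; an optional
Nelder-Mead polish is off by default. During fitting, a `kcat_2D6` override
replaces the activity-score value verbatim while the unmodified compound
keeps anchoring the capacity normalisation, so the override moves exactly
one term. Dose matching bisects geometrically on dose (morphine exposure is
monotone in dose) to 2% and rounds to a 5 mg increment, warning above the
240 mg labelled daily maximum.

## Synthetic observed data

The evaluation and calibration machinery needs "observed" mean
concentration–time profiles of the kind digitized from published figures;
no public accession of such data exists, so the `synthetic` module
generates them: the engine simulates ground truth at a sparse clinical grid
(default 0.25–24 h, 12 points), applies multiplicative log-normal residual
error with unit median (default CV 20%, typical assay plus biological
variability for plasma opioid assays) per subject and time point,
optionally samples distinct virtual individuals, and reports arithmetic
means per time point with the generating parameters in a truth sidecar.
Passing tests against these data demonstrate internal consistency
(parameter recovery, unbiasedness, fold-error behaviour of the machinery) —
not agreement with real clinical profiles, which would require the
digitized literature data themselves. Note that arithmetic means of
log-normal noise converge to exp(σ²/2) ≈ 1.02 × truth at CV 20%; the tests
assert exactly that.

## Problem sizes

Default study conditions are those of the modelled scenarios: single-dose
simulations run 24 h on the reference individual; the dose-equivalence
scenarios are EM 30 mg, IM 80 mg, PM 1500 mg, UM 20 mg tablets in the Asian
reference. The headline Monte-Carlo recovery uses n = 2000 random-search
samples against a 12-subject, 20%-CV synthetic study; auxiliary
single-parameter recovery checks use n = 400, and population demonstrations
in the test suite sample 8–1000 individuals (band simulation uses the
smaller sizes, pure sampling the larger).

## Known limitations

* Demethylcodeine and the glucuronides (C6G, M3G, M6G) are elimination
  sinks; their kinetics (including active M6G) are out of scope, as are
  pharmacodynamics, drug–drug interactions, transporters, enterohepatic
  recirculation, food effects and nonlinear protein binding.
* Physiology covers healthy adults 18–65; no paediatric/geriatric
  ontogeny, pregnancy or organ impairment. Ethnic references differ only in
  body size.
* Multiple-dose regimens are supported mechanically (repeat doses at an
  interval), but the published multiple-dose exposure convention (interval,
  duration) is not documented; no multiple-dose quantity is calibrated.
* The oral-absorption chain is a deliberately minimal standard
  reconstruction; regional intestinal enzyme expression and solubility
  limitation are not modelled.
* Genotype (star-allele) to activity-score translation is outside the
  package; activity scores are inputs.
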