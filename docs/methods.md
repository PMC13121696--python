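# Methods and design notes

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Study design encoded in `StudyConfig`

Time zero is drug/vehicle administration, 30 min after bilateral thigh
impact; the baseline blood draw carries negative time (−1.5 h by default,
impact at −0.5 h). Scheduled chemistry/urine draws: baseline, 0, 2, 6, 12,
18, 24, 48 h. Iohexol (5 mL of a 647 mg iohexol/mL formulation, i.e. a
3235 mg dose by default) is injected at 1, 19 and 43 h with post-dose
samples at 15, 30, 90, 120, 180, 240 and 300 min; with the 5 h sampling
window these injections measure GFR at roughly 6, 24 and 48 h of protocol
time, and the pipeline maps the last two injections to the "24 h" and
"48 h" GFR used for the recovery slope. Potassium strictly above
5.0 mmol/L at any scheduled draw triggers one protocolized hyperkalemia
intervention. Arms: no-impact (n=6), vehicle (n=9), cilastatin (n=21; the
pooled treatment arm).

## Measured GFR (`pk_gfr`)

Model: two-compartment bolus kinetics, C(t) = A·e^(−αt) + B·e^(−βt) with
α > β > 0, fitted by unweighted nonlinear least squares on linear
concentrations (an optional 1/C² weighting is config-exposed; no weighting
is the default because none is standard for this assay). Initialisation is
classical curve stripping: log-linear fit of the terminal half of the
points gives (B, β); a log-linear fit of the early positive residuals gives
(A, α). AUC = A/α + B/β in closed form and GFR = dose/AUC; with dose in mg
and concentrations in µg/mL (= mg/L) the quotient is L/min, reported in
mL/min.

"Poor fit" has no universal definition; here a two-compartment fit is
declared poor when any of the following holds, each exposed in
`ModelSelectionPolicy`:

* the optimizer fails to converge;
* a parameter is pinned at its positivity bound (relative tolerance 1e-6);
* α/β < 3, i.e. the phases are not separable;
* the corrected AIC prefers the one-compartment fit.

On a poor fit the monoexponential C(t) = C₀·e^(−kt) is used (AUC = C₀/k).
These criteria are conservative and reproducible, and they route the
degenerate case (truly monoexponential data) to the fallback, where the
estimate is exact.

Each injection is fitted independently. Residual carryover from earlier
injections is ignored by default: at the ≥18 h spacing between injections,
more than ten terminal half-lives elapse at normal GFR. A baseline-
subtraction option exists for severely reduced clearance. Bolus mixing is
idealized as instantaneous; the first sample at 15 min makes truncation of
the distribution phase acceptable.

The invariants GFR·AUC = dose and scale equivariance hold by construction
and are asserted in tests on every fit, noisy or not.

## Renal outcomes (`renal_outcomes`)

Rapid recovery: Cr(48)/max(Cr) **strictly** below 0.70, the maximum taken
over all scheduled samples including baseline. The strict inequality
follows the endpoint's "recovery to <70% of maximal creatinine" phrasing
and is configurable. The companion 30%-creatinine-recovery flag records
Cr(48) ≤ 0.70·max (a drop of at least 30% from peak). Missing 48 h samples
yield an explicit missing status; nothing is imputed.

A priori exclusions: impacted animals whose baseline→6 h CK rise falls
strictly below a threshold are excluded as failed impacts. The study prints
the group means of the excluded (27 ± 10) and included (61 ± 4) animals but
not the cut itself; the default threshold 40 sits between those means and
is config-exposed. CK deltas are treated unit-agnostically (the printed
units are ambiguous between IU/kg and IU/L); the rule only compares a delta
against a threshold in the same units. Baseline physiologic outliers
(creatinine, plasma myoglobin, potassium by default) are excluded when
strictly more than 2 SD from the cohort baseline mean.

Urinary indices: fractional excretion of myoglobin
FE = (U_Mb/P_Mb)/(U_Cr/P_Cr); 48 h porphyrin excretion is the trapezoidal
time-integral of the creatinine-normalised porphyrin concentration over the
sampled window (µg porphyrin/µg creatinine × h).

## Hyperkalemia events (`event_protocol`)

One intervention per scheduled measurement strictly above threshold —
continuous monitoring between draws is not modeled, so "immediately
treated" is resolved to the draw time. The Kaplan–Meier estimator is the
standard product-limit Ŝ(t) = Π(1 − dᵢ/nᵢ) over distinct event times with
right-censoring; ties pool at their event time. The log-rank statistic uses
the pooled-risk-set expectation and hypergeometric variance at each event
time, referred to χ²(1). Subjects without an intervention are censored at
48 h; death before 48 h censors the intervention clock at death. First
events only (no recurrent-event machinery); intervention *burden* is
summarised separately as median (IQR) counts with ratio-of-medians
contrasts reported to one decimal.

The asymptotic χ²(1) null reference for the log-rank test is accurate at
moderate group sizes; the calibration test uses 30 subjects per group,
where the simulated type-I error sits inside the exact binomial 99% band.

## Core statistics (`stats_core`)

* Welch t from summaries, with Welch–Satterthwaite df. Printed "±"
  dispersions in group summaries are treated as SDs where the n-consistency
  of the reproduced p-value demands it (the 48 h porphyrin comparison is
  reproducible only under the SD reading).
* Fisher's exact test: full hypergeometric enumeration in exact integer
  arithmetic; the two-sided p is the probability-mass rule (sum over tables
  no more probable than observed), the same convention as R's
  `fisher.test`. Ties at the observed probability are exact, not
  floating-point. A zero margin returns p = 1 by convention.
* χ² for 2×2: N(ad−bc)²/(r₁r₂c₁c₂), optional Yates correction.
* Šidák: p_adj = 1 − (1−p)^m; m is always an explicit argument because the
  per-family comparison counts are analysis choices, never inferred.
* Median/IQR: linear interpolation between order statistics (the most
  common quantile convention), fixed and documented.

The recovery contrast is reported with both the exact test and χ²: for the
reconstructed 12/21-vs-1/9 table the exact two-sided p is 0.0417 and the
uncorrected χ² gives 0.0197; the exact value matches the published figure
at printed precision.

Group-trajectory comparisons (the mixed-models regressions used for the
longitudinal figures) are deliberately **not** reimplemented: the pipeline
exports tidy per-timepoint tables suitable for external mixed-model tools.
Headline mixed-model group means are therefore outside what this package
reproduces.

## Trial power (`trial_power`)

Per simulated trial, recovery counts are drawn Binomial(n, p) per arm
(defaults p_treat = 0.571, p_ctrl = 0.111 — the observed rapid-recovery
proportions) and tested with the uncorrected χ², substituting the exact
test whenever any expected cell is below 5 (or a margin is zero); rejection
at α = 0.01 two-sided. The curve runs over even totals 20–200 (1:1
allocation), 500 replicates per n by default, smoothed by a monotone
(isotonic, PAVA) fit before the minimal-n readout at 90% power — a monotone
fit matches the intent of a smoothed power curve without asserting a
parametric form.

The closed-form cross-check is the standard two-proportion normal
approximation (pooled variance under H₀, unpooled under H₁); at p₁ = p₂ it
returns α by construction. It is a large-sample oracle: agreement with the
simulator within Monte Carlo error is asserted on per-arm sizes ≥16, inside
the approximation's validity (at smaller n the exact-test substitution makes
the simulated test conservative and the comparison meaningless).

The published recommendation of 124 patients total was derived from
unpublished patient input data; with the study's own observed proportions
the simulated power at 62 per arm is ≈100%, so 124 is treated as a
lower-bound consistency check (power at 124 must exceed 90%), not as a
number this package can reproduce exactly.

## Synthetic cohorts (`synthetic_cohort`)

The study published no generative model; the generator is this package's
own construction, chosen so that every downstream estimator has a
well-defined ground truth.

* **GFR trajectory**: baseline (Normal(100, 10) mL/min, floored at 5)
  until impact; exponential decline (time constant 2 h) to an injured
  level — a 65% drop for impacted animals, half that severity scaled by
  0.7 for no-impact animals (anesthesia/immobility AKI); linear recovery
  from 24 h, capped at baseline. Each animal draws a latent Bernoulli
  "recovers rapidly" with per-group probability (defaults 0.571 treated,
  0.111 control, 0.80 no-impact); recovering animals use the per-group
  recovery rate (2.0–2.7 mL/min/h), non-recovering animals 10% of it. These
  rates place recovered animals' 48 h creatinine ratio ≈4 SD below the 0.70
  boundary and non-recovered ≈0.95, so the latent status is recoverable by
  the classifier in every arm — a deliberate identifiability property of
  the generator, verified in tests.
* **Creatinine**: one-compartment mass balance dCr/dt = G/V − (GFR/V)·Cr
  with G = 1.2 mg/min and V = 24 L (0.6 × 40 kg body water), integrated
  exactly over 0.25 h steps of piecewise-constant GFR; steady state
  Cr = G/GFR reproduces the inverse creatinine–GFR coupling (baseline
  ≈1.2 mg/dL at 100 mL/min). Multiplicative lognormal noise, CV 3%.
* **Iohexol**: forward two-compartment model with V₁ = 3 L, k₁₂ = 0.05,
  k₂₁ = 0.04 min⁻¹, elimination k₁₀ = GFR/V₁ (α/β ≈ 10, comfortably
  identifiable); mean-one lognormal noise, CV 5% (a typical LC–MS/MS assay
  CV). With k₁₂ = k₂₁ = 0 the model degenerates to the monoexponential.
* **Potassium**: dK/dt = rise·φ(t) − relax·(K − 4.0) with a saturating
  release curve φ(t) = 1 − e^(−t/3 h) (potassium release from lysed muscle
  saturates faster than CK accumulation), per-group rise (2.0 vehicle, 0.7
  cilastatin, 0.5 no-impact mmol/L/h) and relaxation 0.5 h⁻¹; each
  triggered intervention drops the state by 0.8 mmol/L. Additive Gaussian
  noise (SD 0.12) truncated at zero. These magnitudes reproduce the study's
  qualitative structure: all impacted animals trigger treatment by 6 h,
  no-impact animals only after 12 h, and treated animals need fewer
  interventions.
* **CK**: baseline 250 IU/L plus a saturating rise (τ = 18 h) to ≈17,000
  IU/L in impacted and half that in no-impact animals; lognormal CV 8%.
* **Myoglobin/porphyrin**: plasma myoglobin follows the CK rise curve with
  a late (>12 h) reduction in treated animals; urinary myoglobin follows
  the fractional-excretion identity with a treated-arm multiplier in the
  first 6 h. Creatinine-normalised porphyrin excretion is constant per
  animal at rate 1.096 µg/µg/h × group multiplier (1.0 vehicle, 2.1
  treated, 0.3 no-impact) × a mean-one lognormal between-animal factor
  (σ_log = 0.55), giving 48 h totals near 53 (vehicle) and 110 (treated)
  with between-animal CV ≈ 0.59, matching the reported dispersion scale.
* **Urine output**: exponential approach from 3.6 to 0.5 mL/kg/h (τ = 8 h,
  oliguria); the first post-drug sample in treated animals is multiplied by
  1.67 (the transient diuresis).
* **Seeding**: one master seed; each animal's substream derives from
  `SeedSequence([seed, crc32(animal_id)])`, so enlarging a group never
  perturbs existing animals and identical configs are bit-identical.

What the generator does **not** emulate: hemodynamics (MAP, heart rate,
temperature), fluid-balance physiology, anesthesia effects, histology,
mortality, within-day circadian structure, or any correlation between
baseline characteristics and treatment response. Passing tests therefore
demonstrate that the *estimators and tests* behave correctly under the
assumed data-generating structure — not that the structure captures real
porcine physiology beyond the qualitative features listed above.

Exact treatment doses for the hyperkalemia protocol are not public; the
generator models only a configurable potassium drop per intervention.

## Problem sizes

Defaults were chosen so a complete run is comfortable on a laptop: the
power grid uses 91 sample sizes × 500 replicates; the parameter-recovery
studies use 200 synthetic animals (GFR, 5% noise) and 1000 seeded cohorts
(recovery proportions); calibration studies use 2000–5000 replicates.
Acceptance-level recomputation (`scripts/acceptance.py`) simulates 4000
trials by default.

## Known limitations

* The one-compartment fallback underestimates AUC (hence overestimates
  GFR) when data are genuinely biexponential but poorly identified; the
  `fallback_used` flag is carried through all outputs so such fits can be
  audited.
* The exact-test substitution makes the per-trial test conservative at
  small arm sizes; simulated power at n ≲ 12 per arm is below the normal
  approximation.
* Recovery-proportion denominators use all non-excluded animals with a
  48 h creatinine; animals lost before 48 h would appear as explicit
  missing outcomes and are absent from the generator.
* The baseline-outlier exclusion uses the simulated cohort's own mean/SD,
  so ~2–5% of animals are excluded by construction under clean baselines;
  this mimics the study's a priori screening rather than any pathology.
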