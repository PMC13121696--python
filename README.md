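# crushkit

Quantitative analysis pipeline for a randomized, blinded large-animal
(porcine) efficacy study of cilastatin sodium in traumatic crush syndrome —
rhabdomyolysis-induced acute kidney injury (AKI) with hyperkalemia managed
under 48 h of protocolized critical care.

The package is written for biostatisticians and translational researchers
who need the study's quantitative machinery as tested, reusable code:

* **Measured GFR from iohexol plasma clearance** (`crushkit.pk_gfr`).
  Iohexol is cleared only by glomerular filtration; after an intravenous
  bolus its plasma concentration follows the two-compartment biexponential
  C(t) = A·e^(−αt) + B·e^(−βt). The curve is fitted by curve-stripping
  initialisation plus bounded nonlinear least squares, with a
  one-compartment fallback for degenerate fits, and

      GFR = dose / AUC,  AUC = A/α + B/β.

* **Renal outcome classification** (`crushkit.renal_outcomes`). The rapid
  AKI-recovery endpoint — creatinine at 48 h strictly below 70% of the
  maximal creatinine — plus a priori exclusions (insufficient creatine-kinase
  rise after impact; baseline physiologic outliers beyond 2 SD), GFR
  recovery slopes, fractional excretion of myoglobin and 48 h
  creatinine-normalised porphyrin excretion.

* **Hyperkalemia intervention analysis** (`crushkit.event_protocol`).
  Protocol activations (K⁺ > 5.0 mmol/L at a scheduled draw), Kaplan–Meier
  product-limit curves and the two-group log-rank test, implemented from
  first principles and cross-checked against `lifelines`.

* **Core inference** (`crushkit.stats_core`). Welch's t (including from
  printed summary statistics), exact 2×2 inference by hypergeometric
  enumeration, the 2×2 chi-square, Šidák multiplicity adjustment and
  median/IQR summaries — each from its defining formula.

* **Clinical-trial power** (`crushkit.trial_power`). Monte Carlo power for a
  two-arm binary rapid-recovery trial with a closed-form two-proportion
  cross-check and a monotone (isotonic) power curve with minimal-n readout.

* **Synthetic cohorts** (`crushkit.synthetic_cohort`). A seeded generator
  reproducing the study's structure — arms of 6/9/21 animals, the
  baseline/0/2/6/12/18/24/48 h sampling schedule, iohexol injections at
  1/19/43 h, biexponential tracer decay with assay noise, creatinine coupled
  inversely to GFR through a one-compartment mass balance, and potassium
  trajectories with protocolized treatment drops — so the entire pipeline is
  testable without any animal data.

## Worked example

The numbered drivers under `analysis/` run the full study analysis on the
default synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_classify_outcomes.py
python analysis/05_group_statistics.py
python analysis/06_trial_power.py
```

`05_group_statistics.py` recomputes the study-level inferences from the
printed group summaries and prints:

```
recovery 12/21 vs 1/9: exact p = 0.0417 (chi-square 5.44, p = 0.0197)
porphyrin Welch: t = -2.46, df = 27.0, p = 0.0205
first-hour urine output 67% greater after cilastatin
impact animals required 1.4x the interventions (medians 10 vs 7)
crush induction rate 88% (45/51)
```

i.e. 12 of 21 treated vs 1 of 9 control animals met the rapid-recovery
endpoint (exact two-sided p ≈ 0.042), and treated animals excreted about
twice the heme-derived porphyrin over 48 h (Welch p ≈ 0.02).
`06_trial_power.py` prints the trial-design result:

```
minimal total enrolment for 90% power at alpha 0.01: 60 (30 per arm)
simulated power at 124 total (62/arm): 1.000
analytic normal-approximation power at 62/arm: 0.9994
```

With the observed effect size, an enrolment of 124 patients (62 per arm)
exceeds 90% power at α = 0.01 by a wide margin; the minimal enrolment shown
is specific to these input proportions.

A `crushkit` command-line entry point exposes the same stages
(`crushkit --seed 1 all`, `crushkit gfr --iohexol series.csv`,
`crushkit power --reps 500 --seed 7`).

## Layout

```
src/crushkit/      library modules (generator, PK fitting, outcomes,
                   events, statistics, power, pipeline, CLI)
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and study-level checks)
scripts/           acceptance computation
docs/methods.md    modelling and design notes
```
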