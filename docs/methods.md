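# Methods

## Pharmacokinetic model

The simulator uses the Schnider covariate-adjusted three-compartment
propofol model: a central (plasma) compartment V1 with metabolic clearance
CL1, a fast peripheral compartment (V2, CL2) and a slow one (V3, CL3), plus
a massless effect compartment whose concentration Ce relaxes toward plasma
at rate ke0:

    da1/dt = r(t) − (k10 + k12 + k13)·a1 + k21·a2 + k31·a3
    da2/dt = k12·a1 − k21·a2
    da3/dt = k13·a1 − k31·a3
    dCe/dt = ke0·(a1/V1 − Ce)

with k10 = CL1/V1 etc. Covariates: V1 = 4.27 L and V3 = 238 L for everyone;
V2 and CL2 fall linearly with age (centered at 53 y); CL1 depends on weight,
James lean body mass and height; CL3 = 0.836 L/min. Concentrations are in
mcg/mL ≡ mg/L; rates in mg/min; the drug solution is 10 mg/mL propofol.
The model is not validated in late pregnancy and no pregnancy correction is
applied; results are bench estimates, not clinical predictions.

### Effect-compartment variant (`ke0_mode`)

Commercial effect-site pumps implement the Schnider effect compartment in
two ways: a fixed ke0 = 0.456 min⁻¹, or a patient-specific ke0 chosen so the
effect-site peak after an intravenous bolus occurs 1.6 min after injection
(the time-to-peak-effect convention). Both are implemented; **`tpeak` is the
default** because only it reproduces the induction-dose scale observed on
the studied pump: for the mean cohort patient it predicts boluses of
~104/158/218 mg at Ce-targets 4/6/8 mcg/mL, whereas fixed-ke0 predicts
~79/119/158 mg — about 35% lower, with correspondingly shorter pauses —
regardless of the bolus-rate setting. The patient-specific ke0 is solved by
bisection on the closed-form impulse response (the peak condition is
Ce = Cp). A caveat inherited from this convention: for heavy, high-clearance
patients the solved ke0 becomes small (≈0.15 min⁻¹ at 130 kg) and induction
doses grow steeply; see "Known limitations".

### Numerics

State propagation is exact: each piecewise-constant infusion interval is
advanced with the matrix exponential of an augmented system that also yields
the forced response and the eliminated mass, so mass balance
(dose = compartments + eliminated) holds to float precision and pause
durations carry no step-size error beyond the 1 s decision grid. The
fine-step Euler integrator used to cross-check it in the tests agrees to
better than 0.01% on a bolus-decay scenario. Concentrations are exactly
linear in the infusion schedule; tests assert this at 1e-12.

## Pump controller

Decisions are made every `update_interval` (default 1 s). At each instant
the controller evaluates, on a 10-minute look-ahead grid, the future Ce
trajectory u0(s) + r·u1(s) — zero-input response plus unit-rate forced
response, both closed-form — and applies the largest rate r (capped at the
pump's bolus rate) for which the predicted peak never exceeds the target.
A predicted peak exactly on target counts as resumable. This one rule
produces:

* **induction** — the admissible rate is far above the cap, so the pump
  boluses at the cap until the predicted Ce peak touches the target, then
  waits while Ce coasts up (the plasma peak coincides with the bolus end);
* **maintenance** — the rate settles to CL1·target plus distributional
  losses (the steady-state rate equals CL1·target to machine precision);
* **the infusion pause** — after a target reduction any input would overshoot,
  so the rate is zero until Ce decays to the new target. The resume time
  matches a brute-force fine-step search within one update interval.

The bolus rate cap is the single calibrated knob: **720 mL/h of 10 mg/mL
solution (120 mg/min)**, chosen once so that the mean patient's plasma peak
at Ce-target 8 lands at the ~20 mcg/mL the studied pump displays (21.4 in
simulation); cohort dose, pause and delivery-proportion summaries are nearly
insensitive to the cap between ~560 and 1200 mL/h. `ce_tolerance`
(default 0.5%) only pads boundary comparisons; the controller steers to the
target itself.

One behavior knowingly differs from the studied hardware: at pause end this
controller immediately re-boluses the central compartment (~8–10 mg in a few
seconds) to hold Ce exactly at the maintenance target, whereas the studied
pump visibly ramps its rate up from near zero, delivering under a milligram
in the first ~20 s after resuming. The pause durations agree; the cumulative
dose table therefore shows its first visible step one minute earlier here.
The firmware's ramp profile is undisclosed, and guessing it is out of scope.

## Study protocol

Each case: induce from a drug-naive state at Ce-target 4, 6 or 8 mcg/mL;
detect the plasma peak (first local maximum of Cp, equal to the bolus end
within one grid step); set t0 = peak + 60 s, the assumed moment of tracheal
intubation and surgical incision; step the target down to 2.5 mcg/mL at t0;
record the cumulative dose at t0 and at each minute t0+1…t0+10, the pause
duration from t0 to pump reactivation, the dose at delivery
(tD = t0 + the patient's incision-to-delivery time, interpolated on the
grid) and the flag `delivered_during_pause` (strict inequality: delivery
exactly at reactivation counts as after the pause). The per-case horizon is
30 min; traces are economically truncated after the dose table and delivery
unless the pump has not yet resumed, in which case the full horizon is
simulated and a still-silent pump is flagged rather than failing the cohort.

## Synthetic cohort

Each variable is an independent truncated normal at the study population's
moments (age 32.3 ± 4.3 y, height 164.8 ± 5.9 cm, weight 82.8 ± 17.5 kg;
incision-to-delivery 7.2 ± 3.3 min elective, 4.7 ± 2.6 min emergency;
29/21 elective/emergency split). Truncation bounds keep draws physiologic —
age [16, 55] y, height [140, 200] cm, weight [40, 160] kg, delivery time
[0.5, 25] min; the bulk of each distribution is untouched, so realized
moments shift only slightly (overall delivery-time mean ≈ 6.2 vs 6.1 min
untruncated). A single master seed is split into one child stream per
variable (`SeedSequence.spawn`), making cohorts bit-reproducible and each
variable independently regenerable.

What the generator does **not** emulate: covariate correlation (height and
weight are sampled independently, so derived BMI has a wider spread than a
real population's), gestational covariates, and any association between
urgency and demographics. Consequently cohort-level dose summaries inherit
the model's convexity in weight: per-kg induction doses average ~0.1–0.25
mg/kg above the mean-patient values because both light and heavy virtual
patients need more drug per kilogram than mid-weight ones (fixed V1/V3, and
the tpeak-ke0 falloff at high clearance). Passing cohort-level tests
therefore demonstrates the pipeline's behavior under these stated
conditions, not agreement with any particular real case mix.

## Statistics

Reporting conventions follow the study: Wilson score intervals for
proportions (printed whole-percent bounds are reproduced under outward
rounding — floor the lower, ceil the upper); pooled-variance Student t tests
accepting either raw samples or (n, mean, sd) summaries (the two paths agree
exactly for moment-matched samples); chi-square without continuity
correction when all expected cell counts reach 5, Fisher's exact test
otherwise; logistic regression via maximum likelihood with Wald CIs on the
odds-ratio scale, predictors urgency/age/BMI (BMI instead of height and
weight to avoid collinearity), perfect separation flagged instead of
reported; OLS with R² for incision-to-delivery time. The real study's
regression magnitudes (ORs ≈ 5.8, R² = 0.20) depend on its private
per-patient data; the pipeline reports its own synthetic-cohort analogs and
checks direction and CI coverage only.

## Design choices where the design was open

* Incision is equated with t0, so tD = t0 + incision-to-delivery.
* Delivery exactly at pump reactivation counts as not during the pause.
* A predicted Ce peak exactly on target counts as "resume" (deterministic
  boundary).
* Mid-transient re-targeting needs no special casing: the controller always
  re-predicts from the current state, which is exactly the study's scenario
  (the target drops ~1.6 min after infusion start, before Ce settles).
* The simulation horizon is 30 min per case; cohort-level acceptance
  summaries use 20 seeds × 50 patients × 3 targets (≈40 s on one CPU),
  sizes chosen so Monte-Carlo error is well inside the reported SDs.

## Known limitations

* Heavier patients (>110 kg) receive steeply growing per-kg doses under the
  tpeak variant; whether real pump firmware bounds ke0 there is unknown.
* The post-pause rate profile differs from the studied hardware (see
  controller section); minute-dose tables shift by one bin accordingly.
* No pharmacodynamic (EEG/BIS) layer, no co-medication, no placental
  transfer; plasma-targeting mode and Marsh/Eleveld parameterizations are
  extension points only.
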