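# Methods

## Overview

`trunksleep` implements an objective sleep-assessment pipeline for 24-h
tri-axial trunk accelerometry of the kind recorded by ambulatory Holter
devices (31.25 Hz, ±3 g, 10-bit), together with a synthetic-cohort
generator that stands in for the proprietary recordings such pipelines are
normally developed on. The stages are:

1. **Component separation.** Each axis is split into a gravitational
   component (GC) — the zero-phase low-pass part, reflecting the gravity
   projection and hence upper-body posture — and a bodily-motion component
   (BMC), the residual. Reconstruction `gc + bmc = input` is exact by
   construction.
2. **Minute features.** Non-overlapping 1-min windows yield trunk tilt
   angles `arccos(−mean_gc_axis / ‖mean_gc‖)` per axis (0° = axis aligned
   against gravity, so an upright trunk has vertical tilt 0° and a
   horizontal trunk 90°) and *TPower*, the `log10` of the total
   within-window BMC variance (trace of the covariance). The trace is
   rotation-invariant, so TPower measures movement intensity regardless of
   device orientation. Windows whose mean GC magnitude falls below 0.2 g
   are flagged invalid (sensor fault), never silently dropped.
3. **Sleep–wake classification.** An RBF-kernel support vector machine on
   (three tilt angles, TPower) labels each minute sleep or wake. Sleep is
   the positive class, following the actigraphy convention. Cross-validation
   is grouped by subject so minutes from one subject never straddle a
   validation split.
4. **Sleep scoring.** The in-bed period [IBT, GUT) is detected from the
   features; within it, sleep onset is the start of the first 10
   consecutive sleep minutes, SL = onset − IBT, WASO = wake minutes in
   [onset, GUT), TIB = GUT − IBT, TST = TIB − SL − WASO,
   SE = 100·TST/TIB. Nights with no qualifying onset run are flagged
   `onset undefined` and excluded from parameter tables rather than scored
   with a degenerate latency.
5. **Cohort analysis.** Generalized linear models over
   {normal, gamma} × {identity, log, inverse, inverse squared} are ranked
   by AIC; the chosen model tests age-group, gender and recording-month
   effects with an age×gender interaction, Bonferroni-adjusted pairwise
   contrasts of each age decade against the 20s reference, and α = 0.01.

## The synthetic cohort

The generator emulates what matters statistically about a large ambulatory
cohort, not the physiology of individual nights.

**Per-subject schedule.** One contiguous nocturnal in-bed block per 24-h
record. Population bedtime is 23:34 and rise time 7:31 for the 20s group
(the latest-timed decade); above age 20, bedtime advances 20.1 min per
decade and rise time 14.9 min per decade; WASO grows 4.1 min per decade
above age 30 from a base of 25 min; women go to bed 30.7 min later with an
unchanged rise time, shortening TIB/TST by that amount. These defaults are
the configured *study conditions*; every one of them is a `CohortConfig`
field. Sleep latency and WASO are gamma-distributed (shapes 2.0); subject
heterogeneity enters as Gaussian intercepts on bedtime (SD 40 min) and
rise time (SD 30 min), truncated at 3 SD so a 24-h record started between
10:00 and 12:00 always contains the whole night.

**TIB U-shape.** Group-mean TIB in adult cohorts is U-shaped with its
nadir in middle age. Since two of {IBT, GUT, TIB} determine the third, the
package keeps the *bedtime* trend strictly linear (that is the slope the
recovery analysis estimates) and carries the U-shape as per-decade
deviations added to the rise time (`tib_curve`, +30 min in the 10s down to
−40 min in the 40s and back to +15 min in the 80s). Consequences: the
group-mean TIB curve has its nadir in the 40s, and the realized GUT trend
is deliberately nonlinear — fastest advance into middle age, then
flattening — so no single "GUT advance per decade" describes it and none
is reported.

**Within-night structure.** After the all-wake latency, wake returns in
bouts with gamma-distributed lengths (mean 4 min, shape 1.5) summing
exactly to the drawn WASO; sleep gaps between bouts are allocated
multinomially with the first gap at least 10 min, which guarantees that
re-scoring the truth labels with the truth block reproduces the stored
parameters exactly (this is asserted over 1,000 subjects).

**Signal synthesis.** Upright minutes project gravity to (0, 0, −1) g;
lying minutes are supine with gravity in the antero-posterior axis plus a
per-subject random tilt (SD 4°, capped at 8° so the lying vertical GC
stays within 0.15 g of zero). Bodily motion is zero-mean Gaussian noise
with per-axis, per-minute variance set by behavioural state — 2×10⁻² g²
ambulatory daytime, 5×10⁻⁴ g² quiet wakefulness in bed, 10⁻⁵ g² sleep —
with lognormal minute-to-minute jitter (σ = 0.3). Quiet in-bed
wakefulness sits far closer to sleep than to daytime activity because a
person lying still produces almost no trunk acceleration; that is exactly
the regime that makes wake-in-bed detection the recognized weak point of
actigraphy. Gaussian sensor noise (SD 0.01 g per axis) is added, then the
signal is clipped to ±3 g and quantized to the 10-bit grid (LSB
6/1024 g).

**What the simulator does not model** — and hence what passing tests do
not show about real data: daytime naps (a single nocturnal block is
generated), gradual posture transitions and intermediate postures,
non-Gaussian movement bursts with autocorrelation, device re-positioning,
seasonal signal beyond the month metadata field, and any ECG content (the
noise-beat inclusion criterion is represented by a simulated metadata
fraction). Classifier accuracies near 99% on this clean generator
demonstrate pipeline correctness, not field performance; validation
against polysomnography or wrist actigraphy cannot be replaced by
simulation.

## Numerical and design choices

- **Low-pass filter:** 4th-order Butterworth, zero-phase
  (forward–backward), default cutoff 0.3 Hz — low enough to exclude gait
  (≈1–3 Hz) while passing postural transitions. Configurable.
- **TPower floor:** variance floor ε = 10⁻⁶ g² inside the log, so silent
  minutes map to −6 rather than −∞.
- **In-bed detection:** lying = vertical tilt > 60°; rest = TPower below a
  per-record threshold chosen by a 2-class Otsu split of the minute TPower
  distribution (adapts to each record's activity scale); the block is the
  longest run of lying-and-rest minutes tolerating interruptions ≤ 10 min,
  verified against brute-force enumeration; blocks under 120 min are
  rejected as "no in-bed period". Half-open convention [IBT, GUT); clock
  times reported to 1-min resolution (HH:MM).
- **Classifier:** `SVC(kernel="rbf", class_weight="balanced")` behind a
  `StandardScaler`, grid over C ∈ {1, 10} (γ = "scale") chosen by grouped
  3-fold CV on F1; training minutes above 4,000 are subsampled (stratified,
  seeded) to keep the quadratic fit tractable. An optional majority filter
  over predicted labels exists but is off by default — no temporal
  rescoring is part of the method.
- **AIC convention:** AIC = 2k − 2·logL with *full* maximum likelihood —
  Gaussian variance at its MLE, gamma shape profiled out by solving
  log a − ψ(a) = mean(y/μ − log(y/μ)) − 1 — and the dispersion parameter
  counted in k for both families, so AIC is comparable across them.
  Candidates whose IRLS fit fails, diverges, or drives a gamma mean
  non-positive (possible under identity/inverse links) are recorded with
  their failure message and excluded from selection.
- **Significance testing:** the age×gender interaction and the main
  effects are judged by the scaled-deviance F test
  (F = ΔD/(Δdf·φ̂), φ̂ = Pearson χ²/df of the full model) at α = 0.01.
  The plain chi-square likelihood-ratio test is also provided, but with an
  estimated dispersion it measured anticonservative in a null-cohort
  simulation (≈3% rejections at nominal 1% over 200 replicates, versus
  ≈1.5% for the F test, which is exact for the normal family); the F test
  is therefore the default analysis path.
- **Stratification:** a significant interaction triggers simple main
  effects — age contrasts within each gender (Bonferroni over the 7
  non-reference decades) and gender contrasts within each age group
  (Bonferroni over the 8 groups). One parameter × one stratification is
  one multiple-testing family.
- **Clock-time responses:** bedtime is modelled as minutes from midnight
  shifted by +12 h so the nocturnal distribution does not wrap; group
  means of clock times are averaged on the shifted scale and mapped back.
- **Normality diagnostics:** Kolmogorov–Smirnov, Cramér–von Mises and
  Anderson–Darling against a normal with estimated mean/SD, with
  parametric-bootstrap p-values (`scipy.stats.goodness_of_fit`; default
  199 Monte-Carlo samples — note the smallest achievable p is
  1/(n_mc+1), so decisions at α = 0.01 need n_mc ≥ 199), plus q–q plot
  coordinates.
- **Inclusion screen:** duration > 20 h (strict), age 10–89 inclusive,
  noise-beat fraction < 0.10, whole-record mean vertical GC > −1.0 g
  (strict: a record pinned at −1 g indicates an unworn or misworn device).
  Every failed criterion is reported.

## Problem sizes

The validation suite and the acceptance script run on one CPU in a few
minutes by choosing sizes where each property is already decisive:
accounting identities and truth self-consistency over 1,000 simulated
nights; onset-rule and in-bed-detection oracles over 1,000 and 500 random
sequences; end-to-end recovery (raw signal → parameters) over 50
full-resolution subjects with a 25/25 train/held-out split; cohort effect
recovery at n = 2,000; AIC selection consistency over 50 replicates at
n = 2,000; type-I calibration over 200 null cohorts of n = 400. These
sizes are the package's declared test conditions; all are parameters of
the respective functions and scale up directly.

## Known limitations

- The in-bed detector assumes one nocturnal rest block; shift workers,
  split sleepers and nappers would need a multi-block extension.
- The Otsu rest threshold needs both active and restful minutes in the
  record; degenerate records raise an explicit error.
- Gamma fits under identity and inverse links rely on IRLS staying in the
  positive-mean domain; such candidates may legitimately drop out of the
  AIC comparison for some data sets.
- Bonferroni control is per parameter × stratification family; no
  across-parameter multiplicity control is attempted.
- Clock arithmetic assumes recordings shorter than 48 h and minute
  resolution throughout.
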