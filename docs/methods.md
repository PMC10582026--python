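# Methods

This note documents the models behind `ergocal`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Indirect calorimetry

Substrate oxidation is recovered from gas exchange with the standard
two-equation stoichiometry (coefficients in `calorimetry.py`):
`fat = 1.67·V′O₂ − 1.67·V′CO₂ − 0.307·Pox` and
`cho = 4.55·V′CO₂ − 3.21·V′O₂ − 0.459·Pox`, rates in g·min⁻¹, gas in
L·min⁻¹ STPD. The 2 × 2 linear map in (V′O₂, V′CO₂) is invertible
(determinant ≈ 2.238), which the generator exploits to encode a known fat
rate into V′CO₂ and which the tests use as a round-trip oracle.

Raw rates are *signed*: at RER > 1 the fat equation goes negative (net
lipogenesis / bicarbonate buffering, not oxidation). All reporting layers
clip at zero and set a `clipped` flag; the signed raws stay retrievable.
High-intensity fat oxidation is thus reported as negligible, never negative.

**Protein oxidation.** Pox is estimated as 12 % of energy expenditure
divided by the energy density of protein (16.74 kJ·g⁻¹) — there is no
urinary-nitrogen measurement in this setting. Which EE the 12 % applies to
is context-dependent, and the package uses two conventions deliberately:

* *Basal and graded-test analysis*: Pox is fixed at the subject's
  resting value (12 % of resting EE). Stage-level substrate curves then
  treat Pox as a small constant correction.
* *Prolonged submaximal sessions* (`session.window_rates` default): Pox is
  derived per 5-min window as 12 % of that window's Weir EE. During
  45 minutes of exercise, whole-body protein turnover scales with energy
  turnover, and only this convention yields the ~12 % protein share of
  session energy that session-level substrate tables report; a constant
  resting Pox would put the protein share near 2 %. Passing an explicit
  `pox` restores the constant-rate behaviour.

**Energy.** Substrate energies use 16.7 kJ·g⁻¹ (CHO and protein) and
37.7 kJ·g⁻¹ (fat); the session total is their exact sum, so grams × factor
reproduces the energy columns identically. Resting EE uses the Weir
equation without protein correction (`4.184 × (3.941·V′O₂ + 1.106·V′CO₂)`
kJ·min⁻¹) — the standard choice for ventilated-canopy calorimetry, isolated
in one function so an alternative can be swapped in.

**BMR analysis** discards the first 10 min of the 45-min canopy recording
(adaptation to the hood) and averages the remainder. The discard length is
a parameter; every discard is logged with counts.

## Graded-test analysis

* V′O₂peak: mean of samples in the half-open-from-the-left window
  `(t_end − 20 s, t_end]` — exactly 4 samples at 5-s breath averaging.
  The mean (not median) is used. HRpeak is the same-window HR mean,
  rounded to 0.1 bpm; O₂ pulse = 1000·V′O₂peak/HRpeak, reported to 0.1.
* Stages: each completed 5-min stage is summarised over its final 60 s
  (half-open window), where gas exchange has plateaued; stages with < 60 s
  of data (test stopped at the HR criterion) are excluded with a warning.
  Intensity = 100·V′O₂/V′O₂peak of the *same* test.
* MFO/Fatmax: default `stage_max` takes the maximum clipped stage fat rate
  (ties toward the lower intensity), mirroring per-workload determination.
  A `poly3` option fits a least-squares cubic of fat rate on intensity and
  maximises it on the observed range, for smooth curve-level estimates.
  Note that a max over noisy stages is upward-biased by selection; the
  stage grid, not the estimator, sets the resolution of Fatmax.
* Crossover: the first downward crossing of the clipped fat-rate curve
  through 0.05 g·min⁻¹ at intensities above Fatmax, linearly interpolated
  between stages. The threshold is a package choice (configurable): the
  underlying observation is qualitative ("negligible"), so any small
  positive cut is defensible; 0.05 g·min⁻¹ is ~1 % of energy supply at
  these workloads. Interpolating across wide stage gaps overestimates the
  crossing of a convex decline — a stage-resolution limit, not a bug.

## Prescription

Both arms are equated to 20 kJ per kg FFM of *conditioning* energy
(≈ 1.4 MJ at these fat-free masses). Segment energy is predicted as
V′O₂(intensity) × duration × 20.9 kJ·L O₂⁻¹; 20.9 is a conventional round
equivalent near RER ≈ 0.9, and an RER-dependent equivalent
(`oxygen_energy_equivalent`) is available. The COMB session is
5′ @ 50 % + 3 × 2′ @ 95 % + 2 × 1′ @ 50 % + MICT @ 60 % with the moderate
duration solved in closed form against the budget. The warm-up is part of
the delivered session (it appears in the plan, its time counts toward the
HIIT share denominator) but *outside* the energy budget: with it inside,
the solved moderate block shrinks to ~26 min and the session to ~39 min,
inconsistent with the ~30-min moderate block and ~43-min structure the
design describes; treating warm-up as preparatory reproduces that design.
The MICT arm is one continuous block, default 40 % V′O₂peak; passing the
subject's Fatmax intensity instead trains at maximal fat oxidation, both
usages are supported because trial descriptions differ on this point.
HR targets come from linear interpolation of the subject's own stage
(intensity, HR) pairs, extrapolated with the top two stages and clamped at
HRpeak.

## Session analysis

Consecutive half-open 5-min windows over the exercise phase; the trailing
partial window is kept with its true duration (dropping it would bias
totals low). Totals are window rate × window minutes; grams and kJ are
reported to integer precision in the table view. Training load uses an HR
cut at 85 %HRmax to classify time as HIIT vs MICT (the conventional HIIT
definition); the two shares sum to 100 exactly. When a planned session is
supplied to the CLI, planned segment labels are available in the outputs,
but the HR-cut classification is what makes recorded and planned sessions
comparable.

## Trial statistics

Classical mixed-design sums of squares (between: group; within: time),
computed in closed form and cross-checked in the tests against both a
brute-force design-matrix oracle and `pingouin.mixed_anova`. With two
repeated measures sphericity holds trivially (ε = 1); the Greenhouse–
Geisser ε is implemented generically for k > 2 so the module is reusable.
The Bonferroni post-hoc family is the four cell contrasts actually
reported (within-group W0 vs W3 × 2, between-group per timepoint × 2),
multiplier 4, computed when the interaction is significant at 0.05.
Degenerate error-free inputs yield F = ∞, p = 0 rather than a crash.
Hedges g applies the small-sample correction `1 − 3/(4·df − 1)` to the
pooled-SD standardized difference; labels: small < 0.20 ≤ medium < 0.50 ≤
large.

## Synthetic generator

The generator emulates the *study conditions*: group-level presets
(anthropometrics, BMR, V′O₂peak, HRpeak, fat-curve landmarks, session
substrate totals) with means and SDs taken from the trial population of
male adolescents with severe obesity, at two timepoints per arm.

* **Subjects** are independent truncated normals per cell (no BM–FFM
  covariance beyond FFM ≤ 0.95·BM; a documented simplification — real
  anthropometrics correlate strongly).
* **Fat-curve truth** is a scaled beta-shaped unimodal function of
  intensity with three landmarks (MFO, Fatmax, crossover) and shape
  exponent q = 0.5, giving the broad plateau and steep final decline seen
  in walking fat-oxidation curves. Only the landmarks are
  population-anchored; the family is a package choice made for positivity
  and single-peakedness.
* **Gas traces**: per-segment steady targets with mono-exponential onset
  kinetics (τ = 40 s); V′CO₂ is back-computed from the truth curve through
  the stoichiometric inverse, so analysis recovers the curve. Noise:
  multiplicative CV 4 % on V′O₂/V′CO₂ per breath-averaged sample, additive
  3 bpm on HR, RER capped at 1.1. BMR recordings carry an adaptation
  transient over the first 8 min that is identically zero afterwards, so
  the 10-min discard rule is exercised and noiseless recovery is exact.
* **Stage intensities** for the graded protocol are fixed fractions
  (30, 40, 50, 60, 72, 86, 100) % of the subject's V′O₂peak — a realistic
  light-to-peak walking progression chosen once; the published protocol
  fixes speed/incline, not per-stage intensity. The stop rule evaluates a
  30-s smoothed HR against 180 bpm (a clinician watches a trend, and an
  unsmoothed rule would truncate on single noise spikes).
* **Sessions**: segment steady states are solved so the substrate-sum
  energy per minute equals the planned segment energy, keeping simulated
  sessions on their designed budget. A per-preset `session_fat_gain`
  multiplier (1.0–1.35) scales the fat-curve truth during prolonged
  sessions only; it emulates the well-documented upward drift of fat
  oxidation with exercise duration and is calibrated once against the
  session substrate tables — without it, no unimodal curve bounded by the
  group's MFO can reproduce the reported session fat (whose implied average
  rate exceeds the graded-test MFO). It is a calibration constant, not a
  measured quantity.
* **Cohorts**: paired W0/W3 draws with within-subject correlation
  ρ = 0.8 (exposed as a parameter because ANOVA power depends on it;
  anthropometric retest correlations are typically higher, so simulated
  change-score SDs for body mass are wider than a real trial's).

**What passing tests show — and don't.** Pipeline-recovery tests show the
analysis is *consistent with its own generator* (identifiability under the
stated noise), and calibration tests show group summaries match the preset
targets. They do not validate cart hardware behaviour (drift, breath-by-
breath artefacts, flow-sensor nonlinearity), day-to-day biological
variability, or the BIA regression (which is an injection point, never
implemented here).

## Numerical conventions

Time is seconds from recording start; every window is half-open
[start, end) except the V′O₂peak window, which is half-open from the left
so it includes the final sample. Means are plain arithmetic means of the
samples in the window. The COMB energy solve is closed-form (no iteration);
the generator's session fixed point runs to a 1e-12 relative tolerance.
All randomness flows through `numpy.random.Generator` seeds; identical
(preset, noise, seed) triples are bit-reproducible.

## Problem sizes

Default validation sizes were chosen to make Monte-Carlo error small
relative to the tolerances being checked: 200 replicates for recovery and
calibration properties (SE of a mean ≈ SD/14), 1000 replicates at
n = 1000/group for the ANOVA type-I calibration, 10 000 draws for
population-mean checks. All are package choices and parameters of the
respective functions.

## Known limitations

* No ventilatory-threshold or plateau-based V′O₂max criteria — the test
  deliberately stops at HR ≈ 180.
* No EPOC/recovery modelling; session analysis covers the exercise phase.
* The BIA FFM equation and BMI-SDS growth references are pluggable hooks;
  the package validates, but cannot reproduce, external body-composition
  values.
* Between-group clinical outcomes of a real cohort (e.g. body-mass change)
  are population facts, not desk-reproducible quantities; the package
  covers them only as generator-calibration properties.
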