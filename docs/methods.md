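# Methods

This note records the models, numerical choices and known limits of
`vestgait`, in the order data flow through the pipeline.

## The kinematic walker

The simulator is a template walker, not a biomechanical model: its purpose
is to provide trajectories whose gait events and parameters are known in
closed form so every downstream stage can be tested against exact truth.

* The pelvis marker (SACR) advances at constant speed
  `v = step_length × cadence / 60` with sinusoidal lateral sway
  (amplitude 0.02 m) at stride frequency, at a height equal to leg length.
* Foot strikes alternate every step time τ = 60/cadence s; footprints
  advance by the step length (split 2a/(1+a) : 2/(1+a) when the left/right
  asymmetry ratio `a` ≠ 1) at lateral offsets ±step_width/2.
* From strike to foot off (a fraction `s` of the stride, the stance
  fraction) heel and toe are exactly stationary on the ground. During
  swing the foot translates rigidly along a monotone cubic Hermite
  profile with a single-hump vertical heel lift (0.05 m).
* The swing foot lifts off and lands with a nonzero horizontal speed,
  twice the pelvis speed by default (`contact_speed_ratio`). Real heels
  contact the ground with forward velocity; numerically, this choice makes
  the slopes of the heel-to-pelvis distance symmetric about the contact
  instant (+v before, −v after), so its extremum falls exactly on the true
  event and is unbiased under any symmetric smoothing. A profile with zero
  terminal velocity (e.g. a cycloid) would instead bias coordinate-based
  detection several frames early, an artefact of the template rather than
  of the detector.

Symmetric timing fixes total double support at `2s − 1`; a spec value
conflicting with that identity is rejected rather than ignored. Ground
truth (event frames and the 13 per-cycle parameters) is computed from the
continuous template; event frames are rounded to the sample grid, so any
single recovered timing can differ from truth by up to one frame
(10 ms at 100 Hz) by construction. Noise (isotropic Gaussian, default 0)
and dropout are applied after the truth is recorded. Back-and-forth
walkway passes are generated as separate straight passes, one per
direction, which excludes the turns from analysis.

What the walker does **not** emulate: within-trial cycle-to-cycle
variability (the template is perfectly periodic, so per-trial SDs are
zero up to noise), foot rotation during roll-off, vertical pelvis
oscillation, soft-tissue artefact, and turning gait. Passing tests on
this generator demonstrates correctness of the computational chain, not
robustness to every pathology of real recordings.

## The cohort sampler

`generate_cohort` plants group structure statistically rather than
kinematically. Per-cycle dimensionless parameters are drawn as
`group mean + subject intercept + cycle noise`, with the published
group-level mean and SD per parameter and speed as defaults. The `icc`
parameter (default 0.5) is the between-subject share of each published
variance: the subject intercept has variance `icc·sd²`, the cycle noise
`(1−icc)·sd²`. The value was fixed once by the prescribed Monte-Carlo
calibration — with the published comfortable-speed group means and SDs at
n = 10 per group, the mixed model must detect the group effect in ≥ 95% of
replicates (measured 98% over 200) — and lies within the usual range of
between-subject variance shares for spatiotemporal gait parameters.

Clinical scores are truncated-normal draws: FGA items from a subject
ability on the 0–3 scale (integers, summed to the total), TUG seconds and
tandem steps from the published median/range summaries (SD ≈ range/4,
tandem rounded to half steps), DHI from the mean/SD of the published
per-patient values, fixed at 0 for healthy subjects. Bounds are enforced
by truncation, so no draw can leave its instrument's range.

## Marker IO and gap filling

Trials are stored in a long-form CSV dialect (`frame,marker,x_m,y_m,z_m`,
empty fields = missing, header comment carrying the sample rate and trial
identity); coordinates are converted to metres on read (`mm`/`cm`
supported) and missing samples are flagged, never zero-filled. Required
markers are LHEE, RHEE, LTOE, RTOE and SACR; absences are reported by
name.

Gap filling uses the inter-correlation structure of the marker set: for a
gap no longer than `max_gap_frames` (default 50 = 0.5 s at 100 Hz), the
gapped marker's coordinates are regressed on the principal components of
all markers observed throughout the gap, fitted over the frames where both
are visible, and the regression predicts the gap. All components above
numerical rank are kept, so on rigid or near-rigid motion the
reconstruction is exact (hold-out RMSE ≪ 1 mm on a rigid cluster); gaps
of ≤ 5 frames with fewer than 3 reference markers fall back to linear
interpolation. Longer or unsupported gaps stay missing and are reported.
Observed samples always pass through bit-identical.

The laboratory frame is never assumed: the walking direction is
re-estimated per trial from the net pelvis displacement, and all spatial
parameters are computed in the plane relative to that axis, making the
pipeline invariant to rotating or translating the capture volume and
uniform across walkway directions.

## Event detection and self-selection

Both detectors operate on zero-phase Butterworth-filtered signals
(2nd order, applied forward-backward).

* **coordinate** — strikes at local maxima of the travel-projected
  heel-minus-sacrum distance, offs at local minima of toe-minus-sacrum;
  extrema are first located on the filtered signal (default cutoff 10 Hz)
  and then refined to the argmax of the raw signal within ±5 frames,
  which removes the residual bias the filter introduces where the swing
  profile's curvature is asymmetric around the contact kink (measured
  ~0.6 frames at high cadence with a 6 Hz cutoff, < 0.2 frames after
  refinement). A peak position needs far less noise suppression than a
  derivative, which is why this detector's default cutoff is gentler than
  the classic 6 Hz.
* **velocity** — stance is where the smoothed horizontal foot-centroid
  speed (6 Hz cutoff) is below a threshold, default 10% of the mean pelvis
  speed. The raw crossing of a low threshold sits several frames inside
  the smeared speed edge, so the stance mask is first cleaned
  morphologically (swing gaps < 0.15 s closed, stance blips < 0.20 s
  dropped) and each boundary is then refined to the centre of the edge —
  the extremum of the speed derivative within ±0.08 s — which is unbiased
  under zero-phase smoothing. Measured accuracy: ≤ 1 frame with 3 mm
  marker noise.

A minimum spacing of 0.35 s between same-kind events caps detectable
cadence at ~171 steps/min, above any self-selected overground walk.

`select_events` runs every detector on both sides and scores each event
train by the unweighted sum of three terms in [0, 1]: fraction of
left/right-alternating strike pairs, 1 − coefficient of variation of
stride times (clipped), and fraction of per-side stance estimates inside
55–75 %GC. The highest score wins; scores within 0.01 are treated as tied
and resolved by the fixed order (coordinate, velocity), since differences
at that level are sampling noise rather than evidence. Strikes violating
alternation in the winning train are QC-flagged, not deleted, replacing
the visual event check of an operator with an auditable log.

## Cycles and parameters

A cycle spans consecutive ipsilateral strikes and must contain exactly
one contralateral off, contralateral strike and ipsilateral off, strictly
in that order; violations (or overlap with a configured exclusion window,
e.g. a walkway turn) invalidate the cycle with a machine-readable reason.
Footprints are heel-marker horizontal positions at strike frames. Step
length is the projection of the contralateral print onto the ipsilateral
line of progression; step width the perpendicular distance to it (an
identical initial/terminal print leaves that line undefined and
invalidates the cycle). Timing parameters follow from the five event
frames; stance + swing = 100 exactly by construction, and
single + double = stance up to frame quantization. Cadence is computed
per cycle (120/stride time) so that every record is cycle-local — the
unit of observation the mixed model expects; trial cadence is the mean
over cycles. Both sides are pooled by default with a side filter
available. The six parameters beyond the canonical seven are stride
length, stride time, step time, swing %GC, stride speed and the
step-length asymmetry ratio (second step over first step of the cycle).

## Dimensionless scaling

With leg length L0 and gravity g (default 9.81 m/s², configurable):
lengths ÷ L0, times ÷ √(L0/g), speeds ÷ √(g·L0), cadence in steps/min
× √(L0/g), percentages and ratios unchanged. Keeping cadence on its
per-minute basis is the convention under which v̂ = ŝ·ĉ/60 holds exactly
and dimensionless cadence lands in the published 26–42 range. The record
carries (L0, g) so the inverse transform is exact (round-trip within
1e-9 relative). Body mass is recorded in the anthropometry but no
parameter in this set depends on it; no mass scaling is invented.

## Group statistics

* **Kruskal–Wallis + Dunn.** H with tie correction (scipy); Dunn's
  pairwise z-tests on mean ranks with the usual tie term
  Σ(t³−t)/(12(N−1)), two-sided, reported raw and FDR-adjusted. Groups
  with fewer than two observations are excluded with a flag.
* **Mixed model.** Per speed stratum and parameter: REML linear mixed
  model (statsmodels MixedLM) with group fixed effect and participant
  random intercept; the default scipy optimizer is used deliberately —
  L-BFGS collapses the random-effect variance to zero on these designs.
  The group test converts the Wald statistic to F with denominator
  degrees of freedom `n_subjects − n_groups`. For balanced designs this
  equals one-way ANOVA on subject means exactly (verified numerically),
  which makes the test exactly calibrated there; measured type-I error
  0.034–0.045 over 500-replicate nulls. Kenward–Roger-style corrections
  would refine unbalanced small samples but are not available in the
  stack; the containment df is the documented choice. Pairwise contrasts
  are t-tests on the fitted coefficients with the same df. With one
  observation per subject the random intercept is unidentifiable and the
  model falls back, flagged, to ordinary ANOVA; zero-variance outcomes
  are flagged with no p value.
* **FDR.** Benjamini–Hochberg step-up by default (Benjamini–Yekutieli
  selectable), applied across the full family of speed × parameter group
  tests, and separately across each outcome's post-hoc pairs.
* **Shapiro–Wilk** annotates normality per group/outcome; it never
  switches the test.

## Two-step clustering

Continuous variables only, z-scored first (a zero-variance variable is an
error naming it; an all-identical case set short-circuits to one
cluster). Pre-clustering inserts cases sequentially into a flat list of
CF entries (count, sum, sum of squares): a case joins the nearest entry
if the log-likelihood distance of the merge is below the threshold, else
opens a new entry; exceeding the leaf cap (default 100) rebuilds the list
with a doubled threshold. A multi-level CF tree would change nothing at
cohort scale (n ≈ 30) and is not implemented. Case order is fixed by
subject id for reproducibility; order sensitivity of the pre-cluster
stage is documented, not emulated.

The distance follows the published SPSS formulation,
`d(i,j) = ξᵢ + ξⱼ − ξ_{i∪j}` with
`ξ_v = −N_v Σ_k ½ log(σ̂_k² + σ_vk² + 10⁻⁸)`, where σ̂_k² is the overall
variance of variable k (it keeps singleton distances finite) and 10⁻⁸ is
the variance floor. BIC(J) = −2 Σ ξ + 2·J·K·log N for K variables.
Automatic selection uses the published ratio gates (BIC-change ratio
0.04; distance-change ratio 1.15) plus a third, configurable gate: a
solution with more than one cluster must show a minimum-merge-distance
jump of at least 4× over the next split. The extra gate exists because,
with singleton pre-clusters at small n, the agglomerative stage optimises
the same quantity BIC measures, and the ratio gates alone accept a second
cluster on pure 2-D Gaussian noise about half the time; measured jumps
are ≤ ~2.3 (90th percentile) on noise and ≥ 25 for two clusters separated
by 8 within-cluster SDs. The gate makes the automatic k conservative on
weakly separated data — heavily overlapping score distributions often
yield k = 1 where an eager procedure would split; lower the gate to taste
via `min_distance_jump`. Final assignments go to the nearest selected
cluster in log-likelihood distance; on separated data the full pipeline
agrees exactly with brute-force 2-means.

Cases with a missing variable (e.g. one BV patient's absent DHI) are
dropped before clustering and recoverable from the case index; no
imputation is attempted.

## Pipeline

`run(config)` validates options (defaults injected, unknown keys
rejected, g > 0, existing paths), then simulates or loads trials,
processes each (gap fill → detect → cycles → parameters → dimensionless),
fits the statistics, builds the published-table-shaped summaries and the
DHI-vs-FGA clustering, and writes CSV/JSON reports plus an exclusion
audit in which every dropped trial or cycle appears with its reason. Any
stage failure raises an error naming the stage and removes partial
outputs. All randomness flows from the single config seed, and repeated
runs are byte-identical. In simulation mode each subject receives
anthropometry (height ~ N(1.68, 0.08) m, leg length 0.53 × height, mass
from a BMI draw) and per-speed dimensionless targets from the cohort
model; each trial's walker is built from those targets with the subject's
leg length, alternating walkway direction across trials. Plotting is
deliberately out of scope: all reports are plain tables, so no figure can
affect a numeric result.

## Problem sizes used in the checks

The self-contained verification uses: a 27-point grid of gait styles
(step length 0.4–0.8 m × cadence 80–130 steps/min × stance 58–68 %GC) for
noiseless recovery; 500 null cohorts (n = 10 subjects/group, 20
cycles/subject) for mixed-model calibration and 200 replicates each for
the power checks; 100 noise draws (n = 30) for the cluster null; and a
full 30-subject cohort at three speeds × three trials for the end-to-end
run. These sizes give binomial standard errors well inside the asserted
margins while the whole suite completes in a couple of minutes.

## Known limitations

* The walker's periodicity means within-trial variability indices are not
  exercised beyond noise; variability metrics are out of scope.
* The mixed model assumes a single random intercept per participant;
  random slopes or heteroscedastic group variances are not modelled (a
  heteroscedastic null measurably inflates the F test's type-I error).
* The clustering handles continuous variables only; categorical
  extensions and outlier sub-clusters are out of scope.
* Only the documented CSV trajectory dialect is read; binary capture
  formats require prior export.
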