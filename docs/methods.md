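# Methods

## Coordinate convention and data model

All positions are millimetres at a fixed frame rate (default 100 Hz).
Axes: x = subject's left (+), y = superior (+, opening moves toward −y),
z = anterior (+, protrusion moves toward +z). A recording session is one
subject × one task (OC, LL, LR, P) and holds two trajectories: the mandible
(primary) marker and the forehead head-reference marker, equal in length and
rate. Trajectories travel as a small CSV dialect (`# frame_rate_hz:` /
`# units:` header lines, then `time_s, primary_*, head_*` columns); cohorts
are described by a `subject_id,group,movement,file` manifest. Binary
motion-capture formats (C3D/TRC) are out of scope; converting them to the
CSV dialect is the supported extension point.

## Preprocessing

**Head compensation** subtracts the head marker frame-wise. With a single
forehead marker only rigid *translation* can be removed; rotational head
motion is a known, accepted residual. Compensation runs before filtering by
default; because subtraction and a linear filter commute, the opposite order
(exposed as `compensate_first=False`) is numerically identical up to edge
effects.

**Band-pass filter.** A 4-pole Butterworth band-pass, cut-offs 0.01 and
8 Hz (an order-2 design per side — an order-N band-pass has 2N poles),
applied to each axis independently, forward and backward so the response is
zero-phase. Zero phase matters because the deviation features depend on the
*sample index* at which extrema occur; the price is that the effective
attenuation is the squared single-pass magnitude.

Numerical note: the 0.01 Hz high-pass side has a ~20 s time constant, so
scipy's stock `filtfilt` edge handling (short reflected padding plus
steady-state initial conditions) lets edge transients of the slow poles
bleed across an entire 15–60 s record. We instead subtract the straight
line joining the two edge baselines (each estimated as the mean of a 0.5 s
edge window) and run the cascade forward then backward from zero initial
state. A line's spectral content lies almost entirely below the 0.01 Hz
stop-band edge, so this removes only what the ideal filter would remove,
while making both edges start at rest. Measured response (30 s records,
central third): 3 Hz tone → 1.05, 25 Hz tone → 0.011, 10 mm constant → 0
exactly. Linearity holds to 1e-9.

The filter genuinely costs accuracy on finite records: a one-sided
15.5 s pulse train has nonzero spectral mass below 0.01 Hz, whose removal
sags the baseline by a few tenths of a mm across a record. After per-cycle
rebasing this leaves feature errors up to ≈0.45 mm on a 40 mm opening.
Noise-free recovery is therefore *exact* (≤1e-6 mm, verified) only with the
filter bypassed (`filter_enabled=False`); through the full default pipeline
the recovery tolerance is 0.75 mm. This is a property of the specified
cut-offs on finite recordings, not of the implementation.

**Segmentation.** On the task's signed primary-axis signal (OC: −y, LL: +x,
LR: −x, P: +z), cycles are peaks with prominence ≥ 25% of the signal range,
separated by ≥ 0.5 s; each cycle's boundaries are the signal minima of the
adjacent inter-peak (or peak-to-edge) intervals, so the full excursion plus
adjacent rest is kept and the rebasing origin sits at rest. A cycle whose
boundary never drops below 10% of its height above baseline (10th
percentile) is a partial cycle at a recording edge and is dropped. A
mismatch with the expected count (default 6) raises an error stating the
count found. OC cycles carry the index of the −y extremum (earliest sample
on ties) as the opening/closing phase split.

## Features

Eighteen maximum-displacement features, all ≥ 0 mm, means over the
repetitions of each task (the per-feature average is stable by six
repetitions; `reducer="max"` is available). Deviations are measured
relative to the phase's starting position (a vertical reference through the
phase start, `deviation_reference="start_axis"`); measuring from the
straight chord between phase endpoints is available as `"chord"`. ODY/CDY
are the vertical distance from the phase start to the sample where the
respective x-deviation peaks (earliest sample on ties); OCZ/LLZ/LRZ are z
ranges (max − min), which is sign-convention-free; PDX/PDZ are measured
along z, the protrusion progress axis. PDZ is defined as the protrusive
distance to the point of maximum *vertical* deviation (paired with PY);
this asymmetry with PDX (paired with PX) is deliberate and kept as defined.
The identity OCX = ODX + CDX is re-established after averaging by
recomputing OCX from the reduced ODX and CDX, so it holds exactly under
either reducer. Durations and velocities are deliberately not features —
task speed is at the subject's discretion.

## Synthetic cohorts

Real patient recordings are not redistributable, so the generator is the
test bed. Each repetition is an out-and-back path of duration
`cycle_duration` (default 2 s) with progress p ∈ [0, 2]: the primary axis
moves as `A·sin²(πp/2)` (smooth, zero end velocity, extremum A at mid-task)
and every deviation/coupling axis as `D·sin(πp)` (extrema ±D at p = 0.5 and
1.5, where the primary axis is exactly A/2). Every feature is therefore
analytically predictable — OCY = A, ODX = CDX = D, OCX = 2D,
ODY = CDY = A/2, z-range features = 2 × coupling, PDX = PDZ = PZ/2 — and
`truth_features()` returns this ground truth per subject. Repetitions are
separated by 0.5 s of stationary rest.

Sensor noise is a random-phase sinusoid per axis at `sensor_noise_freq`
(default 25 Hz, required to sit above the 8 Hz cut-off) with SD
`sensor_noise_sd`; the default 0.15 mm matches the published linear error
range of optoelectronic jaw trackers (0.1–1.0 mm). An optional constant
head offset (drawn ±30 mm per session) plus linear drift is added to both
markers to exercise compensation. Between-subject variation perturbs each
amplitude by a truncated Gaussian. The four primary amplitudes are floored
at 0.5 mm (an active range of motion is strictly positive, and a task with
no excursion has nothing to segment); opening deviation and sagittal
coupling are floored at 0.3 mm because the *location* of their maxima
defines ODY/CDY/PDX/PDZ, which degenerate to noise when the excursion
vanishes — no real incisor path is perfectly planar.

Group presets are **illustrative**: no group-level feature means were ever
published for a real cohort, so the defaults encode clinical expectations
(controls with full range of motion; myopathy with restricted opening,
laterality and protrusion; arthropathy with marked opening deviation,
left/right asymmetry and irregular vertical coupling) and cannot be
validated against patient data. `study_profiles(separation)` builds
cohorts whose group means differ by `separation` between-subject SDs on
several feature families per group pair — `separation=0` gives identical
groups (a chance-level control), `separation=5` a near-separable cohort.
The generator emulates amplitude structure, band-limited noise and head
offset; it does **not** emulate condylar rotation/translation mechanics,
marker dropout, or realistic inter-feature correlations, so passing tests
demonstrate pipeline correctness, not clinical performance on real data.

## Sample-size study

`required_n` implements n = 2(z_α + z_β)²σ²/Δ² per group (defaults
z_α = 1.96 for a two-tailed α = 0.05, z_β = 0.84 for 80% power), rounded up
with a floor of 2; equal means are infeasible rather than a number. The
pilot-cohort table bootstraps each group's subjects 1000 times, takes the
average bootstrap sample mean and sample SD per feature (n−1 SDs
everywhere in the package), pools the two group SDs as their root mean
square (the formula's equal-variance assumption), and flags feature/pair
combinations whose required n exceeds a threshold (default 10).

## Classifiers

The 1-nearest-neighbour classifier is implemented natively: Euclidean
distances, stable top-k by distance (equidistant neighbours at the
k-boundary keep the earliest training rows), majority vote with ties broken
by smaller mean neighbour distance, then by training-row order — fully
deterministic for the k = 1–4 range of interest. Random Forest
(120 bagged trees), Gaussian Naïve Bayes and the SVM (one-vs-one, kernels
linear/RBF/polynomial, polynomial degree defaulting to 3 since no degree is
standard) delegate to scikit-learn behind the same train/predict contract,
seeded for determinism. The kernel-normal Naïve Bayes — the reporting
default — is implemented here: per-class, per-feature Gaussian-kernel
densities with the normal-reference bandwidth h = σ̂(4/3n)^{1/5}, combined
under the independence assumption with empirical class priors.

## Bootstrap evaluation

Per resample, a model and a validation subsample are drawn independently,
stratified per group, ⌈n_g·fraction⌉ rows with replacement (fraction 0.5 ≈
"half of each group"). Because both are drawn from the same pool, a row can
appear in both — an optimistic bias that is part of the emulated protocol;
`disjoint=True` restricts the validation draw to rows the model subsample
left unused. Features are z-scored once on the full table before
resampling by default (`normalization="pooled"`, reproducing
normalise-then-split leakage); `"per_resample"` refits the scaler on each
model subsample for a leakage-free variant. Metric cells with empty
denominators (e.g. precision of a never-predicted class) are recorded as 0
and counted in a `degenerate_cells` diagnostic so the score matrix stays
rectangular for averaging. One master seed spawns an independent child RNG
per resample index, so reports are bit-reproducible and extending
`n_resamples` never reshuffles earlier resamples; a resample whose model
subsample lacks a class would be redrawn and counted (unreachable under
stratified draws, kept as a guard).

Chance-level behaviour: with identical groups and disjoint validation,
per-class sensitivity averages 1/3, but on any *single* cohort the realised
neighbour geometry biases per-class rates by up to ~±0.15, so chance-level
checks average over several generated cohorts. With the default shared-pool
scheme, 1-NN memorises duplicated rows and chance-level sensitivity rises
to ~0.6 — the quantified signature of the protocol's optimistic bias.

## Problem sizes and test design

The test suite and acceptance script use the 40-subject study layout
(20 CG / 10 MG / 10 AG, four tasks × six repetitions at 100 Hz), 200–1000
bootstrap resamples, and five-cohort averages for chance-level checks —
sizes at which every Monte-Carlo tolerance used in the tests was chosen to
sit several standard errors from its threshold. Known limitations:
translational-only head compensation; segmentation assumes discrete
repetitions separated by rest; the generator's independence of feature
perturbations across families; and the finite-record band-pass sag
quantified above.
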