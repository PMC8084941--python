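# Methods

This note documents the models, conventions and numerical choices behind
flybehave, and what the synthetic generator does and does not emulate.

## Kinematics and conventions

Trajectories are 0-based, frame-contiguous tables of centroid positions
in mm; all intervals are half-open `[start, end)`. Speed is the backward
finite difference of position times the frame rate, with
`speed[0] := speed[1]` (the first displacement is undefined and tracker
conventions vary; duplicating the first defined value avoids an
artificial pause or jump at frame 0). Smoothing is available (centred
moving average of positions before differencing) but **off by default**:
every threshold rule downstream is defined on raw, un-binned
instantaneous speed, and pre-smoothing would blunt single-frame jump
spikes.

Units are fixed internally at mm, s and mm/s; pixel→mm calibration is
the writer's responsibility. Track files are tab-separated with YAML
metadata (fps, arena geometry) on `#` comment lines. Frame gaps of at
most 2 frames are linearly interpolated and flagged, never silently
dropped; longer gaps are an integrity error by default (in non-strict
mode they are interpolated and flagged too — we prefer a single
explicitly-flagged trajectory over silently splitting one trial into
several).

## Courtship segmentation

The analysis window runs from the first courtship frame for 10 min at
the trial's native fps, truncated at copulation and at video end.
`before` covers `[0, first bout start)`; `on` is the union of bouts
intersected with the window; `off` is the window's complement of `on`.
The courtship index denominator ends at copulation when one occurred
(no courtship is scored after copulation); this is an assumption the
annotation format cannot decide and is flagged here. The inclusion
boundary is CI ≥ 0.20, inclusive. The distance proxy is strictly
`distance < 5.5 mm`; ties go to `far`.

## Locomotor states

The published bands (pause < 4, walk 4–50, jump > 70 mm/s) leave
(50, 70] uncovered; a fourth state `fast` absorbs it. `fast` frames
count in the pausing denominator (which is *all* phase frames) but never
in walking means, so mean walking speed is always inside [4, 50] when
defined, and the four state fractions sum to 100%. Band edges follow
the wording: 4 and 50 inclusive for walking, strictly above 70 for
jumps. Consecutive supra-threshold frames merge into one jump event at
the run start, since one take-off can span more than one frame at
60 Hz; a jump straddling a phase boundary is attributed to the phase
containing its onset. Whether jump frames belong in the pausing
denominator is not decidable from the definitions; they are included
(denominator = all phase frames). Rolling speed traces use a centred
15 s window truncated at the trace edges, with no speed-band filter.

## Looming model

θ(τ) = 2·tan⁻¹((l/v)/τ), in degrees, with τ the time to virtual
collision. The nominal object kinematics of this assay (length 1 cm,
speed 25 cm/s, with l the half-length) would give l/v = 20 ms, which is
inconsistent with the assay's 40 ms ratio; 40 ms is the default because
it uniquely reproduces the presentation schedule — expansion over
≈450 ms (closed form:
τ* = (l/v)/tan(39°) = 49.4 ms before collision, i.e. 450.6 ms after
onset) to the 78° cap followed by a ≈50 ms hold within the 500 ms
presentation.

Schedules draw an initial delay and 6 offset-to-onset ISIs uniformly
from [10, 20] s, redrawing the whole schedule if it overruns the 5 min
stimulation window (with the default protocol the maximum span, 140.5 s,
always fits; the rejection loop guards non-default protocols).

"Walking in a 0.5 s bin" (the event-inclusion rule) is operationalized
as ≥ 50% of bin frames strictly inside the 4–75 mm/s band; a bin-level
rule is needed but undefined at frame resolution, and the majority rule
is the least committal choice. It is exposed in
`LoomResponseThresholds.walking_bin_fraction`. Delta-speed bins exclude
individual jump frames (> 75 mm/s) rather than discarding the whole
event. Baseline/stimulation jump counts are raw counts over the fixed
2 min / 5 min windows, not rates.

## Activation epochs

Epoch masks are contiguous half-open blocks of 3 min each from trial
start, truncated at copulation or video end (flagged). Raw speed — no
band filter — is used for all activation quantities, unlike the
courtship walking-speed metric. Recording starts at courtship onset in
this assay, so no before-courtship phase exists.

## Statistical decision tree

Assumption tests run at α = 0.05 (configurable; the gating α is a
package choice). A dataset is parametric only if *every* group passes
Shapiro–Wilk *and* D'Agostino–Pearson (both tests are required and no
standard combination rule exists; conjunction is the conservative
choice) *and* Levene's test passes.
D'Agostino–Pearson is skipped (and flagged) below n = 8, where its
kurtosis moment test is undefined. Constant or n < 3 groups are
non-parametric by fiat.

Dunn's post hoc test is implemented in-package (both forms), since no
pre-installed library provides it: after Kruskal–Wallis it uses pooled
ranks with the standard tie correction; after Friedman it ranks within
subject blocks with z = ΔR̄/√(k(k+1)/(6n)). Both are cross-checked in
the tests against independent re-derivations of the formulas. Bonferroni
correction (p·m capped at 1) applies to every post hoc family, including
the multiple pairwise paired t-tests after RM-ANOVA.

The zero-median reference test draws a normal sample with the group's
standard deviation, median-centres it, and applies the Wilcoxon
rank-sum test — the simplest construction of "random values with median
around zero and variance equivalent to the experimental group". It is
deterministic per seed.

Null simulations (two N(0,1) groups of 20, full dispatch pipeline) put
the empirical type-I error near 0.055 at α = 0.05: the normality
pre-tests route ≈18% of null datasets to Mann–Whitney, and conditioning
on a failed pre-test slightly inflates the combined rejection rate, a
known property of pretest–dispatch procedures.

## Synthetic generator

The generator emulates the study conditions, not fly biomechanics: 60 Hz
recordings (25 Hz supported), a 40 mm circular arena for courtship and
activation, 30 mm for looming.

* **Courtship** (11 min recordings): latency to court is exponential
  (mean 45 s, clipped to 5–120 s); bouts and gaps are exponential
  (means 15 s and 10 s), giving CI ≈ 0.6, well above the 0.20 inclusion
  boundary. Per frame, the female pauses (speed uniform in [0, 1) mm/s,
  exercising the < 4 band) with a phase-specific probability or walks
  (normal draw clipped to the 4–50 band); jump spikes are single frames
  uniform in (75, 120] mm/s so one event type clears both the 70 and
  75 mm/s thresholds. The control profile walks at 11/7/8 mm/s
  (before/ON/OFF) with pausing probability rising through courtship
  (0.30/0.45/0.50) and no jumping — slowing and pausing during
  courtship; the "silenced" escape profile accelerates acutely during
  bouts (11/17/11 mm/s), pauses less (0.30/0.12/0.35) and jumps at
  2/min during ON. During bouts the male holds a pursuit distance of
  ≈3 mm (< 5.5), between bouts 6.5–15 mm.
* **Looming**: baseline walking speed N(10, 1.5) clipped inside the
  4–75 band; each loom inserts a dip (−6 mm/s for 0.5 s) then a surge
  (+15 mm/s for 1.5 s from offset), optionally one jump spike per loom.
* **Activation**: epoch speeds are gamma-distributed with the declared
  means (12/2/11 mm/s by default) and sd 1.5 — gamma keeps speeds
  non-negative with the mean exact, where a rectified normal would bias
  the low-speed epoch upward.

Positions are integrated from the speed trace along a smoothed random
heading; a step that would exit the arena is re-aimed toward the centre,
which preserves the step length exactly, so the speed trace recovered by
differencing equals the drawn trace (up to the `speed[0]` convention).
Each trial derives an independent RNG substream from (seed, trial
index), so batches are reproducible element-wise.

Per-frame states are i.i.d. within a phase — real pausing and walking
have autocorrelated bout structure that is *not* modelled, and no gait,
orientation, song or pheromone dynamics exist. Passing recovery tests
therefore shows that the analysis chain measures what the data contain
at realistic magnitudes and sampling rates; it does not validate the
thresholds against real fly kinematics.

## Problem sizes and tolerances

The validation suite uses n = 20 flies per condition for recovery
(orderings and 2-SEM checks), 10⁵ random frames / ≥10³ random events
for oracle-equivalence, 1000 replicates for type-I calibration
([0.03, 0.07] band at α = 0.05) and 1000 seeds for schedule invariants —
sizes at which Monte-Carlo error is far below the effect sizes being
recovered while the whole suite runs in well under a minute on one core.
Geometry assertions use absolute tolerances of 0.1 ms on the cap time
and 1e-12 degrees on exact angles.
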