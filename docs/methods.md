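# Methods

This note documents the models, conventions, and numerical choices behind
`glucotrial`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable option existed.

## Data model and trace reconstruction

A flash CGM sensor records an interstitial glucose estimate every 15 minutes
into a device buffer holding the most recent 8 hours. Each scan downloads the
buffer contents; the continuous trace is the union of overlapping downloads.
Identical (timestamp, glucose) repeats across downloads are the normal
consequence of scanning more often than every 8 hours and collapse silently;
the same timestamp with different glucose values is treated as a hard
integrity error, since it indicates corrupted input rather than legitimate
overlap. When consecutive scans are further apart than the buffer, the
stretch `(previous scan, next scan − buffer]` was never downloaded; it is
recorded as a gap interval, never interpolated, and no downstream analysis
(peak extents, hypoglycemia runs) bridges a gap.

Timestamps are stored timezone-aware: a UTC instant plus the local offset in
which it was recorded. All day-based metrics (peaks/day, logs/day, weekly
scan medians) use the local calendar day, because eating, scanning, and
annotation are circadian behaviours. Glucose values outside (0, 500) mg/dL
are rejected at parse; the literature gives no reporting floor/ceiling for
the device class, so these bounds are a package convention.

Window slicing uses closed intervals at both ends. This makes the arithmetic
of the standardized meal test exact: a 2-hour window on the 15-minute grid
contains nine samples, and the four tests of a cross-over subject contribute
36 samples.

## The meal-tolerance-test endpoint

Each subject performs a fasted MTT (standard 45-g carbohydrate drink) four
times: at the beginning and end of both cross-over periods. Per test the
incremental AUC is computed over [t₀, t₀ + 120 min] on a grid anchored at t₀
with the trace's nominal step:

- the baseline is the glucose at t₀ — the sample there, or the linear
  interpolation between bracketing samples when t₀ is off-grid (annotations
  need not align with sensor times; the result is flagged);
- increments are glucose − baseline at each grid point, integrated by the
  trapezoid rule;
- the default `positive_only` convention zeroes negative increments before
  integrating (the standard incremental-AUC convention in postprandial
  research); a `net` convention that keeps signed increments is available and
  recorded in every result.

A grid point counts as covered when a sample lies within one nominal interval
of it; the window must cover at least 75% of its grid points or the test is
rejected as insufficient data. Units are (mg/dL)·min throughout — the time
integral of a concentration.

Per arm, ΔAUC = AUC_end − AUC_begin; per subject,
ΔΔAUC = ΔAUC_product − ΔAUC_placebo. A negative ΔΔAUC means the product
blunted the meal response more than placebo did.

## Exact signed-rank test

The cohort test is a one-sided Wilcoxon signed-rank test of H₀: ΔΔAUC ≥ 0
against H₁: ΔΔAUC < 0. Zeros are dropped; absolute values receive mid-ranks
under ties; W⁺ is the sum of ranks of the positive values. For n ≤ 20 the
p-value is obtained by enumerating all 2ⁿ sign assignments of the observed
rank vector, which remains exact under mid-ranked ties (a lookup table of the
untied null would not). Beyond n = 20 a normal approximation with a 0.5
continuity correction is used, with mean Σrᵢ/2 and variance Σrᵢ²/4 of W⁺ —
both expressions valid for arbitrary (mid-)ranks. The result records which
method produced it. Rejection is at p ≤ α.

One documented discrepancy: for the six published pilot contrasts the exact
enumeration gives P(W⁺ ≤ 6) = 14/64 = 0.21875, whereas the pilot publication
prints P = .28 (which equals P(W⁺ ≤ 7) = 18/64 = 0.28125). The convention of
the software used there is unknown; this package documents its own exact
convention and does not adjust toward the printed value.

## Power by simulation

Power for a future design is estimated by Monte Carlo: each replicate draws n
per-subject ΔΔAUC values from N(μ, σ²), applies the signed-rank test at level
α, and power is the rejection fraction with its binomial standard error
√(p(1−p)/n_sim). For n ≤ 20 the exact enumeration null is precomputed once
per run; for larger n the continuity-corrected normal approximation is used,
identical to the scalar test's conventions. The planning inputs mirrored from
the pilot are μ = mean ΔΔAUC of the three responders (−1546.73 (mg/dL)·min)
and σ = sample SD (ddof = 1) of all six ΔΔAUC values (1228.43 (mg/dL)·min);
at n = 35, α = 0.05 one-sided and 20 000 replicates this yields power ≈ 1.0
(the standardized effect is ≈ 1.26). How the original power figure was
computed is not stated in the source; this simulation is the package's
defined substitute.

## Baseline stratification

Subjects are split on the incremental AUC of their first MTT with a plain
cutoff (default 1000 (mg/dL)·min, configurable). On the published pilot
table, any cutoff in (834.8, 1557.6) reproduces the responder/non-responder
grouping; data-driven rules were deliberately not used, because both the
largest-gap rule and 2-means isolate the extreme subject instead of
reproducing that grouping. A cutoff outside the observed range is an error,
so both groups are always non-empty.

## Peak detection

Scoring uses Palshikar's S1 spike function:
score(i) = ½·[max_{j=1..k}(xᵢ − xᵢ₋ⱼ) + max_{j=1..k}(xᵢ − xᵢ₊ⱼ)], with k = 4
samples (one hour each side); boundary points use the available one-sided
neighbourhood. S1 was chosen as the simplest member of the spike-function
family since the original analysis's exact variant and parameters are not
published; every knob is exposed. The trace is smoothed by a centred moving
average (width 3) before scoring, and processed per contiguous segment so
peaks never span a gap.

Candidate points score above mean + h·sd of the positive scores (h = 1);
candidates closer than 60 minutes merge. From each cluster the apex is found
by hill-climbing the smoothed curve to its local maximum (high scores sit on
the steep rise, not at the top), then taking the raw sample nearest that
summit. Extents walk outward along the flanks tracking the running minimum,
terminating where the curve rises more than 5 mg/dL above it (a genuine
valley rather than sensor noise); the local baseline is the higher of the two
flank minima, prominence is apex − baseline, and the reported interval is
trimmed to where the smoothed curve returns within 10% of the prominence
above the baseline. Candidates with prominence below 20 mg/dL are dropped —
at a sensor noise scale of ~5 mg/dL this separates meal excursions from
noisy fluctuation. Overlapping extents are clipped so the returned peaks are
sorted and pairwise disjoint.

On synthetic days with three ≥40 mg/dL meal bumps and noise SD 5, the
defaults recover all injected peaks (sensitivity ≥ 0.95 required, 1.0
observed over 50 seeded days) with no false peaks (≤ 0.5/day required), and
average 2–3 detected peaks per day over a standard three-meal routine.
Published in-peak totals from the original cohort (hours per day in peaks)
depend on unavailable raw traces and are not reproduction targets.

Meal annotations are matched to peaks greedily in time order: each meal
claims the first unclaimed peak starting within [event − 15 min,
event + 90 min]; the negative allowance absorbs post-hoc annotation, the
90-minute default accommodates high-fat meals whose glycemic rise is delayed
by over an hour.

## Compliance metrics

Scan-gap analysis reports all inter-scan intervals, the count exceeding the
8-hour buffer, the total data lost (Σ max(0, interval − buffer) — exactly the
time that aged out of memory), weekly medians on 7-day blocks from the first
scan, and the sign of the first-to-last-week change (study fatigue shows as
+1). The fasting pre-check inspects the 6 hours before an MTT: insufficient
data below 75% grid coverage, flagged when the window's glucose range exceeds
25 mg/dL or a detected peak overlaps it, pass otherwise. The 25 mg/dL
"flatness" limit is a package convention (the behaviour it screens for is
described qualitatively in the source literature, e.g. a 90→130→90 mg/dL
overnight excursion); it is configurable. Annotation rates count logs per
local calendar day over a fixed span with zero days included, reporting the
mean and the variance-to-mean ratio (sample variance).

## Consensus glucose metrics

Time in range is the fraction of samples in [70, 180] mg/dL, boundaries
inclusive; each sample stands for its nominal interval. Hypoglycemic episodes
are maximal runs of samples strictly below 70 mg/dL lasting at least two
consecutive samples (≥30 min nominal); "below 70" is strict while the range
boundaries are inclusive, matching the asymmetric phrasing of the consensus
definitions, and runs never bridge gaps. The postprandial flag takes the
value 2 h after a meal (nearest sample within 15 min, else linear
interpolation) and fires at ≥140 mg/dL. Subject summaries report mean, SD
(ddof = 1), CV, and the three band percentages, which partition 100% of
sampled time exactly by construction.

## Synthetic-data generator

`simulate_trace` produces baseline + circadian + meals + noise on the
15-minute grid: a per-subject baseline drawn from N(95, 10²) mg/dL, a
circadian sinusoid of amplitude 8 mg/dL peaking at 08:00 local (a dawn-phase
rise), additive meal impulses, and i.i.d. Gaussian sensor noise of SD
5 mg/dL with an optional AR(1) knob (interstitial sensors smooth; the
correlation structure is plausible but not specified anywhere, so the
default is independent). Values are clipped to [40, 495] mg/dL with a
warning, keeping hypoglycemia testable without nonphysical readings.

The meal impulse is a gamma-density-shaped curve pinned to its apex: height
carbs_g × 1.2 mg/dL per gram at 45 min post-meal, decayed to 5% of the apex
by 120 min. The shape exponent follows from those three anchors in closed
form, so the apex lies exactly on the grid and the incremental AUC is exactly
linear in the effect multiplier at zero noise — properties the tests exploit.
The magnitudes are conventions chosen to look like textbook postprandial
excursions, not estimates of any real cohort.

Scan behaviour draws log-normal inter-scan intervals around a median (default
5 h) whose weekly multiplicative drift (default 1.1) models study fatigue;
with probability `overshoot_prob` (default 0.05 — overshoots occurred but
were a minority in the motivating study) an interval instead exceeds the
buffer by 0.25–3 h, losing data. Compliant draws are truncated at the buffer
so that only deliberate overshoots lose anything.

`simulate_study` assembles whole cohorts in the package's file formats:
2×2 cross-over designs (14-day periods, 4-day washout, arms alternating by
subject so the arms stay balanced), three jittered meals a day, four MTTs at
07:00 local (breakfast skipped on MTT days, so the preceding fast is ~12 h),
meal/MTT/fingerstick annotations, and scan times. The treatment effect is a
multiplier on the end-of-product MTT response (0.7 by default — a 30%
blunting); per-subject response heights vary as N(1.2, 0.2²) mg/dL per gram.

What the generator does **not** emulate: insulin–glucose dynamics, carryover
effects across the washout, meal-composition effects (fat-delayed
absorption), annotation errors or missing annotations (except by explicit
request), sensor drift and calibration error, or any attempt to fit the real
subjects of the motivating study. Passing tests therefore demonstrate the
correctness and internal consistency of the analysis pipeline under the
stated statistical structure — not the physiological accuracy of the
generator, nor expected performance on real traces whose noise is correlated
and whose meals are irregular.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: 50 one-day traces
for peak recovery, 10 for the peaks/day average, cohorts of 6–8 subjects for
the end-to-end report, n = 200 for parameter recovery, and 20 000 Monte-Carlo
replicates for power estimates (binomial SE ≤ 0.35 percentage points).
Trapezoid integration is validated against an independently coded
midpoint-rectangle refinement to 10⁻⁹ relative error; enumeration p-values
are validated against a subset-sum dynamic program over the untied null and
against an independent exact implementation on tie-free data. Floating-point
tie tolerance in the enumeration comparisons is 10⁻⁹ on rank sums. All
randomness flows through `numpy.random.default_rng` seeds; every generator
operation is reproducible bit-for-bit under a fixed seed.

## Known limitations

- The exact test's p-value convention differs from the unknown software used
  for the published pilot p-value (see above); both conventions cannot be
  matched simultaneously.
- Period and carryover effects are not modelled; the analysis is the paired
  ΔΔAUC contrast only, as in the motivating design.
- Peak-extent definitions (10%-of-prominence return, 5 mg/dL rise tolerance)
  are package conventions; shaded extents in the motivating figures are not
  formally defined there.
- The fingerstick stream is parsed and carried through but no CGM-agreement
  statistics are computed.
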