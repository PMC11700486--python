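# Methods

## Estimands and estimators

The analysis treats a gait study as a three-level hierarchy: subjects,
capture sessions within subjects, and repeat walking trials within
sessions, crossed with a two-level clothing condition (tight / loose).
Each trial contributes one time-normalized joint-angle curve per channel
(4 joints × 3 planes, 101 points covering 0–100 % of a right-sided gait
cycle, degrees).

Three variation levels are estimated per channel as pointwise SD curves:

| level | trials pooled per subject | interpretation |
|---|---|---|
| inter-trial | 5 session-1 trials, one condition | intrinsic repeatability |
| inter-session | 10 trials of sessions 1+2, one condition | adds extrinsic, setup-related variability |
| inter-session-clothing | all 20 trials, both conditions | adds the clothing change |

All SDs use the n−1 denominator.  Cohort curves are the arithmetic mean of
per-subject SD curves — the convention of the gait-reliability literature,
which reports "average variation"; quadratic (RMS) pooling is available
via `subject_pooling="rms"` for sensitivity analysis and is never smaller
than the arithmetic mean (power-mean inequality).  No small-sample bias
correction (c4) is applied to reported outputs; the c4 factor appears only
in the validation oracles, where the true sigma is known.

Scalar summaries are cycle average / min / max / range.  The variability
ratio is computed pointwise, `mean_t[s_IS(t) / s_IT(t)]`, with zero
inter-trial points excluded; computing instead the ratio of the two cycle
averages gives a different number whenever the curves are not proportional
(e.g. curves (1,2) vs (2,2): 1.5 pointwise vs 1.33 ratio-of-means), and
the pointwise definition is what reproduces the internal consistency of
published ratio tables.  The ratio direction is inter-session over
inter-trial, so values above 1 quantify the variability a second session
adds.

The clothing effect is the RMSD between the two conditions' session-1
cohort-mean curves (per channel): subjects' trial means are averaged
within condition, the two cohort curves differenced, squared, averaged
over the 101 points and rooted.  A per-subject variant (RMSD within each
subject, then averaged) is available via `rmsd_per_subject=True`; the two
differ when subjects' condition effects have opposing signs, which the
cohort-level default deliberately averages away.

Grand averages are the mean of the 12 per-channel cycle averages, reported
with the across-channel SD (n−1).  They are computed over the full
101-point cycle, not the stance phase only.

Segment lengths (per-frame Euclidean distance between endpoint positions,
constant within a trial for pose-estimation output) are averaged over the
trials of each session; the inter-session difference is reported as an
absolute value in mm and as a percentage of the session-1 mean, with
cohort mean and across-subject SD per condition and segment.

## Event detection and normalization

Heel strike is the local maximum of heel−sacrum displacement along the
declared travel axis; toe-off the local minimum of toe−sacrum
displacement.  Peaks must clear a prominence of 10 % of the displacement
range; after a first unconstrained pass estimates the cycle length, a
minimum separation of 0.4 median cycles is enforced.  These two defaults
are configurable — the displacement rule itself fixes the events only up
to such implementation constants.  Between consecutive heel strikes
exactly one toe-off is kept (the deepest minimum); fewer than two heel
strikes is a "no complete cycle" error; missing samples overlapping a
candidate peak are an error, never interpolated.

The analysed cycle is the most central one: with calibrated-volume bounds,
the cycle whose mid-cycle sacrum position is nearest the volume centre
along the travel axis (ties to the earlier cycle); without bounds, the
cycle nearest the temporal midpoint.  Curves are linearly interpolated
onto 101 cycle fractions; endpoints are preserved exactly and the
operation is idempotent on already-normalized curves.  No spline option is
offered, keeping behaviour bit-stable.

## Angles and conventions

Joint angles are Cardan decompositions of `R_prox^T R_dist` per frame,
intrinsic X-Y-Z by default (sagittal, frontal, transverse; flexion /
anterior tilt positive), pelvis relative to the lab axes.  The sequence is
configurable because upstream pose pipelines do not document a universal
order.  Angle series are unwrapped (period 360°) to avoid ±180° jumps;
frames with |middle angle| > 89.9° are flagged as gimbal-degenerate.
Units are millimetres and degrees throughout; frame indices are 0-based
internally (1-based formats converted at the boundary); lab axes are
declared in the study manifest (default X = direction of travel, Z = up)
rather than assumed.

## The synthetic generator

A trial curve is `template + subject + session + condition + noise`.
Random curves are band-limited Fourier series with i.i.d. Gaussian
coefficients of variance σ²/K over K harmonics (default K = 6), giving
smooth periodic curves whose pointwise SD equals σ exactly at every cycle
point — white noise would make event detection and normalization
unrealistically easy, since real markerless output is low-pass filtered.
One root seed drives per-entity streams derived by hierarchical counters,
so any subject's data is reproducible independently of cohort size.

Defaults are the study conditions the package targets: σ_trial = 1.3° and
σ_session = 1.5° (inter-trial variation near 1.3° and a sub-degree session
increment, as observed in two-session markerless gait studies of healthy
adults), σ_subject = 4° (between-subject differences dominate repeat-trial
differences), a deterministic constant clothing offset of 1.4° (the
observed average between-clothing RMSD), identical for all subjects — the
simplest model consistent with a cohort-level RMSD summary.  The session
offset curve is drawn per (subject, session) and shared across clothing
conditions and trials: it models recalibration, camera placement and
day-to-day effects common to the whole session, and it is what lets the
between-condition RMSD converge to zero when the condition effect is
null.  Segment lengths use a shank/thigh base of 400/420 mm, 20 mm
between-subject SD, 5 mm session-level and 1 mm trial-level jitter.

What the generator does **not** emulate: pose-estimation error structure,
soft-tissue artifact, video/lighting effects, pathological gait, or
channel-specific variance (one sigma applies to all 12 channels).  Passing
recovery tests therefore demonstrate that the estimators are correct for
the assumed hierarchical Gaussian model, not that real markerless data
satisfies that model.

### Expected values under the design

With n trials per cell, the inter-trial estimate has expectation
`c4(n)·σ_trial` (c4(5) ≈ 0.940).  For the pooled inter-session SD the
design matters: with only k = 2 sessions of n = 5 trials sharing a
session-level offset, the pooled sample variance has expectation
`σ_trial² + (n(k−1)/(nk−1))·σ_session² = σ_trial² + (5/9)·σ_session²`
(one-way random-effects decomposition), *not* `σ_trial² + σ_session²`;
the i.i.d. composition `c4(10)·√(σ_trial²+σ_session²)` is only approached
as the number of sessions grows.  At σ_trial = 1.3, σ_session = 1.5 the
expected pooled SD is ≈ 1.63°, which is what simulations recover.  The
unit suite asserts the exact closed form; the acceptance suite also
carries the i.i.d. composition as a comparison point.

## Numerical choices and degenerate inputs

* Sample SD everywhere with ddof = 1; fewer than 2 curves is an error.
* Subjects lacking the required trials/sessions/conditions for a level are
  excluded with a warning and listed in the results; missing cells are
  reported, never imputed.
* Zero inter-trial points are excluded from the ratio; an all-zero
  inter-trial curve is an error.
* Table CSVs round to 2 decimals; `summary.json` keeps full precision and
  is the single source the table renderer reads, so the two cannot
  disagree.  Output is byte-deterministic for fixed inputs.
* C3D I/O is a minimal Intel-float implementation (points + a 4×4 pose
  rotation section); frame counts are bounded by the 16-bit header fields,
  ample for single walking trials.  Coordinates convert to mm from the
  stored units; storage is float32, so round trips are exact to ~1e-7
  relative.

## Problem sizes used in validation

Monte-Carlo checks run at the full 22-subject design with 20 replicate
studies for parameter recovery, 50 trials per cell for the null-RMSD
limit, 100 replicates at reduced cohort size for the ratio-direction test,
and 7 cadences across 80–140 steps/min for event detection — sizes chosen
to hold Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Variance components are channel-global in the generator; real studies
  show plane- and joint-specific variability.
* The raw-trial pipeline assumes upstream filtering; no smoothing is
  applied before event detection.
* Left-side processing exists in the event detector (`side="left"`) but
  the analysis defaults to right-sided cycles only.
* No ICC / SEM / minimal-detectable-change statistics and no hypothesis
  tests between conditions; the analysis is deliberately descriptive.
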