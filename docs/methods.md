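# Methods

`farrowwatch` implements the behavioral half of a vision-based farrowing
supervision system: everything downstream of the object detector.  The
package takes time-stamped detections of four sow postures (lateral lying,
sternal lying, standing, sitting) and of newborn piglets, and produces a
pre-farrowing warning, a debounced farrowing alarm, piglet counts, and the
evaluation metrics for all of them.  A stochastic simulator generates both
the true sow behavior and the noisy detection streams, so the complete
method can be exercised and tested without any video.

## The warning statistic

Sows show nest-building behavior in the last day before farrowing: activity
and posture changes intensify, then collapse in the final hours.  The
warning statistic is the posture-transition frequency

    f = n / T   [transitions per hour],

where `n` counts label changes between consecutive posture samples.  The
pipeline computes `f` on a sliding window (default 1 h, stepped every
15 min) over a *posture timeline* distilled from the detection stream: one
sample per `posture_sample_interval` (default 20 s), labeled by the
highest-confidence posture detection in that interval, or missing when the
detector emitted none.  Missing samples are bridged — `a, missing, b`
counts one transition iff `a != b` — so detector dropouts do not erase real
posture changes.

Two timescales matter here and pull in opposite directions:

* **Sampling too coarse** collapses consecutive transitions into one
  sample.  At a nest-building rate of 20/h (mean dwell 3 min), 60 s
  sampling counts only ~16.5/h — below the warning threshold — which is why
  the default sample interval is 20 s (bias ≈ λΔ/2 ≈ 5%).
* **Sampling too fine** passes single wrong-label frames straight into the
  transition count (each isolated wrong label adds two spurious
  transitions).  Coarser samples let the per-interval confidence vote
  discard isolated errors.  At the default 20 s interval the statistic
  tolerates wrong-label rates of a few percent; under severe lighting
  artifacts (15%+ wrong labels) the frequency floor rises by tens of
  transitions per hour and a stronger posture debounce than the confidence
  vote would be required.  That regime is a documented limitation, not
  handled here.

## The dual-threshold persistence rule

The warning strategy uses two thresholds on `f`: an upper threshold of
17.5/h (nest-building surge) and a lower threshold of 10/h (pre-farrowing
collapse), each of which must be sustained for more than 5 h so that
ordinary eating/drinking/resting bouts cannot trip the rule.  The state
machine is: idle → upper fired → lower fired, at most one event of each
kind per run.  The lower condition is only armed after the upper event has
fired; otherwise any calm sow (f ≈ 0) would trigger it immediately.

"Sustained above threshold for 5 h" needs care with a windowed count
statistic: hourly counts at a true rate of 20/h are Poisson(20), so
P(count ≥ 18) ≈ 0.70 per window and a rule that demands literally every
15-min series point to clear 17.5/h misses ~75% of genuinely nest-building
sows (Monte Carlo, 10,000 simulated sows).  The default sustain test
therefore treats the condition as an *episode*:

1. the episode opens at the first series point satisfying the threshold;
2. it is abandoned only when the series stays on the *contrary* side of a
   hysteresis band (threshold ∓ 2.5/h) for longer than `grace_hours`
   (default 1.5 h) — estimator dropouts shorter than a rest bout do not
   erase a behavioral episode;
3. the warning fires at the first satisfying point whose distance from the
   episode onset reaches `persistence_hours`, provided the *mean* of the
   series over the trailing persistence span also satisfies the threshold.
   The aggregate condition stops a short high-magnitude burst (a vigorous
   meal) from buying persistence with magnitude; the span condition stops
   it from firing early.

Under the default simulator profile this rule fired on 10,000/10,000
simulated sows, never before the nest-building stage; on stationary
mid-band behavior (12/h) it false-fires on ~0.3% of 72 h streams, and it
rejects 2–4 h activity bursts ≥ 99% of the time.  Rates within the
estimator's noise of a threshold (e.g. a sow sitting at 16–17/h for days)
are inherently ambiguous for any rule with this operating point.  Setting
`hysteresis = 0` and `grace_hours = 0` recovers the strict every-point
reading.  The emitted event records `condition_onset` and `emitted_at`
with `emitted_at − condition_onset = persistence_hours` exactly.

`warning_error` scores an emitted warning against the true onset relative
to an intended lead (default 5 h before farrowing) and flags late
warnings.  Under the default synthetic profile the warning fires near the
start of the nest-building plateau, i.e. with a *longer* lead (~16 h) than
the intended 5 h; the error statistic reports that discrepancy honestly
rather than tuning the profile to flatter it.

## Farrowing alarm, piglet counting, duration

A frame is piglet-positive when at least one piglet box falls in it.  To
keep spurious boxes (an ear or hock flagged as a piglet) from raising false
alarms, farrowing is only declared after `k_consecutive` (default 3)
consecutive piglet-positive frames; `T_start` is the first frame of the
confirming run — the best available estimate of the first birth, biased by
at most `k · frame_interval`.  The alarm flag is 1 exactly when `T_start`
is set, and the alarm message (`"Delivery Begin! Start time: <ISO-8601>"`)
is dispatched exactly once to pluggable alert sinks (console, log, mock
GPIO pin for tests — real LED hardware is out of scope).

Counting uses two per-frame quantities: `cur_num`, the piglet boxes in the
frame, and `detected_num`, the running maximum of `cur_num` — without
identity tracking the running maximum is the only monotone litter estimate
available from counts, and it guarantees DA ≥ CA.  `T_end` is the last
frame that raised the running maximum, declared final only after
`end_quiet_hours` (default 1 h) pass with no new maximum; the farrowing
duration is `D = T_end − T_start`.  A false alarm is counted per episode:
one maximal run of ≥ k piglet-positive frames beginning before the true
onset.

The counting accuracies are frame-summed ratios

    CA = Σ cur_num_i / Σ true_num_i,    DA = Σ detected_num_i / Σ true_num_i,

computed over the farrowing period (frames with at least one true birth);
including the long pre-farrowing stretch would let spurious boxes inflate
the numerator against an empty denominator.  Cohort summaries use
unweighted per-sow means, the reading that reproduces the published
overall accuracies (63.2% / 92.9%) from the embedded 22-pen field table.

## The simulator

`simulate_sow` draws posture transitions from an inhomogeneous Poisson
clock (thinning) whose rate follows a piecewise-linear three-stage
profile, in transitions/hour with times relative to farrowing onset:

| stage | span (h) | rate (default) |
|---|---|---|
| baseline | start … −24 | 8 |
| rise | −24 … −22 | 8 → 20 |
| nest-building plateau | −22 … −2 | 20 |
| collapse | −2 … −1 | 20 → 2 |
| pre-onset quiet | −1 … 0 | 2 |
| post-farrowing | 0 … +24 | 1 → 4 |

The published description of the pattern gives the stage boundaries
(−48/−24/−1/+24 h) and the thresholds but no numeric rate curve; the
defaults above are the package's own choice satisfying the qualitative
shape (normal activity, marked rise then fall, near-quiescence after
farrowing) and the two thresholds, and every knot is configurable.  At
each transition the new posture is drawn uniformly from the three other
postures.  Births start exactly at onset; litter size is truncated-Poisson
(mean 12, min 1) and inter-birth gaps are exponential (mean 15 min) — a
deliberately simple birth process, as no reference model is available.

`apply_detector_noise` renders one detection per frame (default 1 s;
sampling interval is behavior-neutral by design).  Posture outcomes per
frame are mutually exclusive — missed with `posture_miss_rate`, wrong
label (uniform over the three others) with `posture_false_rate`, else
correct — so the configured numbers equal the empirical rates a field
count over frames reports.  Four named presets carry the error rates of a
410-image field test of the reference detector in different lighting
scenarios (e.g. `complex_light`: 6.33% missed / 15.19% wrong postures).
Piglet errors in that test were absolute counts, so presets divide by 410
images for the per-frame false-box rate and additionally by an assumed
8 visible piglets per image (configurable; the true denominator was not
recorded) for the per-piglet miss probability.  Box geometry is plausible
but schematic (an overhead 2.2 m × 1.8 m crate at ~500 px/m); confidences
are U(0.6, 1) for true and U(0.3, 0.9) for erroneous detections.

What the simulator does *not* emulate: piglet occlusion and adhesion (the
dominant cause of the published CA ≈ 63%), temporally correlated detector
errors, sow identity switches, multi-sow pens, and diurnal activity
rhythms.  Passing tests therefore demonstrate the correctness and
calibration of the *decision logic* under the stated noise model, not
field performance of a detector.

## Numerical and interface choices

* Time is float seconds from stream start everywhere; hours only at the
  frequency/reporting boundary.  Sampling intervals are half-open
  `[kΔ, (k+1)Δ)`; boundary events belong to the later interval; confidence
  ties go to the earlier detection.
* `frequency_series` is computed by stamping each (gap-bridged) transition
  with the time of its later sample and counting stamps per window with
  binary search; this is exactly equivalent to recounting every window and
  is tested for exact integer agreement against that brute-force oracle.
* BCE uses the natural logarithm with predictions clipped to
  `[1e−7, 1 − 1e−7]`; a base change would only rescale it.  GIoU loss is
  validated against an independent computational-geometry oracle.
* Precision/recall return `None` on degenerate denominators instead of
  raising or returning 0, so cohort summaries can drop them explicitly.
* Problem sizes used by the shipped end-to-end checks: 50 simulated sows
  over −48…+12 h at 10 s frames for the zero-noise pipeline properties;
  200 24 h streams at 1 s frames for the debounce/false-alarm study;
  12-sow noisy cohorts for the summary script.
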