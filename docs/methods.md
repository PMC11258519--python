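# Methods

## Scope and model

`endofluency` detects surgical interruptions — episodes where the operative
view is lost, the endoscope is withdrawn from the nasal cavity, and the lens
is cleaned — in endonasal endoscopic (EEA) video, and summarizes surgical
fluency from the detected events. The detector is a classical
image-processing pipeline, not a learned model: it relies on the stable
color contrast of the EEA scene (red-pinkish mucosa inside the nose,
blue-greenish drape outside it, silverish instruments and gauze), which
makes it fast on a CPU and independent of training data, at the cost of
sensitivity to unusual illumination or drape colors.

All three defining criteria of an interruption must hold simultaneously;
consequently bleeding that stains the view but does not force a withdrawal
is *not* an interruption, and the detector is designed not to fire on it.

## Dominant-color classification

Frames are reduced to the SRB-G space: every pixel is assigned exactly one
of three labels — S (silver/low saturation), R (red), B-G (blue-green) — so
the three per-frame percentages partition 100%.

**Calibration.** Per video, k-means with k = 3 runs on a pooled pixel
subsample (default: 20 frames evenly spaced through the video, 5,000 pixels
per frame, all seeded). k is fixed at 3 because the scene has three color
populations; whitish gauze folds into S through the labeling rule. The
k-means step itself is scikit-learn's (seeded k-means++ initialization,
n_init = 10, 300-iteration cap, tolerance 1e-4), so calibration is
deterministic given frames and seed. Cluster identities are mapped to labels
by a fixed rule: lowest saturation (max channel − min channel) → S; of the
remaining two, the more red-dominant (largest r − max(g, b)) → R; the other
→ BG. A saved reference (JSON) can be reused across videos recorded with
the same equipment.

Calibration assumes the sampled pixels cover all three populations. If a
video (or synthetic clip) never shows one of them, the three centroids
land inside the populations that are present and one label is systematically
wrong; if the sample is outright degenerate (< 3 distinct colors) the
pipeline falls back to the rule classifier below. When the scene palette is
known — synthetic clips — the exact-palette reference
(`synthetic_data.palette_reference`) sidesteps calibration entirely.

**Classification.** Nearest centroid under squared Euclidean distance in
raw RGB (no perceptual color-space conversion: the rule operates on the
same 8-bit RGB values the thresholds were defined on). Ties break by the
fixed priority S > R > BG. The implementation ranks by
−2·x·c + ‖c‖² (the per-pixel ‖x‖² term is rank-invariant), which turns
per-frame classification into one BLAS matrix product.

**Rule classifier (fallback).** Calibration-free: chroma
(max − min channel) below 60 → S; otherwise hue membership, red window
(295°, 65°] wrapping through 0°, blue-green window [75°, 270°]; hues in
neither window take the nearer window boundary on the hue circle. On the
pure synthetic palettes it reproduces the calibrated classifier exactly
(tested), which is what makes it a usable stand-in when calibration is
impossible.

## Detection rule

With per-frame percentages (S, R, B-G) and deltas (ΔS, ΔR, ΔB-G) against
the profile `lookback` frames earlier (default 1; frames with no comparand
get zero deltas), a frame is a candidate interruption onset when

    ΔB-G > T(Δbg)  AND  ΔR < −T(Δr)  AND  S < T(s)

with defaults T(Δbg) = 35, T(Δr) = 22, T(s) = 32 (percentage points).
Deltas are differences in percentage points, not ratios, matching the
additive form of the rule. ΔS is computed and exported in the audit table
but takes no part in the default rule.

Two deliberate semantic choices are exposed as configuration:

* **ΔR direction.** The rule requires a *decrease* in R alongside the B-G
  rise; the default therefore tests ΔR < −T(Δr). The signed comparison
  ΔR < +T(Δr) (which also fires on small increases) is available as
  `literal_rule=True` for sensitivity analysis; both semantics are tested.
* **T(f) units.** The minimum event length is an absolute frame count
  (`min_event_frames`, default 30 frames = 1 s at 30 fps). At a different
  analysis rate (striding) the value should be scaled by the user; the
  package does not silently rescale it.

## Event segmentation

The candidate flags mark withdrawal *onsets* only — during the withdrawal
the profile is stably drape-colored and the deltas are zero — so events are
grown by a two-state machine: OUT begins at a flagged frame; the event ends
at the first later frame whose red percentage has recovered to
`reentry_r_pct` (default 50%, encoding "endoscope back inside"; hysteresis
avoids chattering on partial recoveries). Provisional events separated by
gaps ≤ `merge_gap_frames` (default 15 frames; flicker while the lens is
wiped should not split one interruption into many) are merged, then events
shorter than `min_event_frames` are discarded. If the stream ends while
OUT, the event is closed at the final frame and logged as truncated.

Events are half-open `[start_frame, end_frame)`, 0-based, so
`duration_frames = end − start` exactly; seconds are always
`frame / fps` with the original (un-strided) frame index. Segmentation is
tested against an independent brute-force enumeration (naive run scan +
pairwise merge + length filter) on hundreds of random series.

## Evaluation and the collaboration model

Ground-truth comparison is reported at two granularities, because summary
accuracies of this kind can be computed either way and the package refuses
to guess a single intent:

* **Frame level** (default): boolean per-frame series from both event
  lists; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
  (TP+TN)/N, reported as percentages. Rates with an empty denominator are
  reported as 100% (nothing to miss). This granularity naturally produces
  the sensitivity/specificity/accuracy triple used to report detector
  performance.
* **Event level**: greedy temporal matching; a predicted event matches the
  earliest unmatched truth event whose overlap is ≥ `min_overlap_fraction`
  (default 0.5) of the truth duration; each prediction matches at most one
  truth event.

**Collaboration.** The human–computer collaborative strategy has a reviewer
vet every detected event; the package models a perfect reviewer. The
reviewer's judgment is whether a detected event captures a real
interruption, so an event is discarded exactly when it overlaps *no* truth
event at all. (Discarding by the event-matcher's 0.5-overlap criterion
instead would delete true-positive frames inside poorly aligned detections,
violating the intended guarantee that review never reduces detected
interruption coverage.) Consequently review never lowers specificity, never
changes the true-positive frame count, and leaves false negatives
untouched — missed interruptions stay missed.

**Fluency.** Frequency and total duration of interruptions are normalized
to 10-minute (600 s) windows, overall and per annotated phase. An event is
*counted* in the phase containing its midpoint (one count per event even
when it straddles a boundary) but its *seconds* are split by exact overlap
(so a phase split conserves interruption seconds; both properties are
tested). `burden_pct = interruption_s_per_10min / 6` is the percentage of
operative time spent interrupted. Group comparisons (t tests, ANOVA) are
out of scope: the summaries are tidy tables for external statistical
software.

## Synthetic scenes

The generator scripts scenes, renders them, and keeps ground truth tied to
the script, not to pixels:

* mucosa mean (200, 40, 60); drape (30, 120, 130); instrument
  (180, 180, 180); blood (110, 15, 25) — config-exposed constants chosen to
  mirror the qualitative scene colors (red-pinkish / blue-greenish /
  silverish) with realistic separation (pairwise distances ≥ ~170 RGB
  units);
* withdrawals swap the full frame to drape color (with optional linear
  transition ramps just outside the scripted interval, so the ground-truth
  interval itself is fully drape);
* occlusions paint the silver color over the stated fraction of pixels
  (row-major from the top), only while the endoscope is in;
* bleeding blends the mucosa toward blood red by the stated intensity —
  darker and redder, but still R-dominant, so bleeding alone must not
  trigger detection;
* i.i.d. Gaussian pixel noise (sd `noise_sd`, clipped to [0, 255]); frames
  are rendered lazily and each frame's noise is seeded by (clip seed, frame
  index), so random access, re-iteration, and regeneration are
  bit-identical.

Default clip size is 480×270 (the 16:9 shape of the 1920×1080 recordings,
scaled for test speed; full HD is supported). Default event scales follow
the detector's own units: withdrawal durations uniform over 30–300 frames
(1–10 s at 30 fps, matching typical clean-and-reinsert episodes and always
≥ the 30-frame minimum event length), occlusion coverage up to 0.6,
bleeding intensity up to 0.9.

What the generator does **not** emulate: camera motion and motion blur,
illumination drift, specular highlights, partial withdrawals, anatomy
texture (frames are flat color fields plus noise). Passing tests therefore
demonstrate the algorithm's logic — thresholding, segmentation, exclusion
rules, statistics — under the stated color model, not clinical-grade
accuracy on real operative video, where calibration quality and scene
variability dominate.

## Numerical choices and degenerate inputs

* Percentages are exact rational counts × 100/N in double precision; the
  partition (S+R+B-G = 100) and delta conservation (ΔS+ΔR+ΔB-G = 0)
  invariants hold to 1e-9 and are asserted on every processed frame in
  tests.
* Classification ties (exactly equidistant pixels) resolve S > R > BG.
* Event files round-trip exactly: frame indices as integers, seconds via
  shortest round-tripping float repr (CSV is re-read with round-trip float
  parsing).
* Empty inputs: empty event lists are valid everywhere (all-zero
  summaries, all-false frame labels); an empty frame stream, a zero-length
  evaluation, or a zero-duration phase is an error, not a silent zero.
* Striding yields ceil(N/stride) frames; timestamps always come from the
  original index, so strided and full-rate analyses of the same video agree
  on event times (event *frame* coordinates are in analyzed-stream units).

## Problem sizes in the verification suite

The test and acceptance runs use deliberately small scenes: clean-recovery
checks on a 10,000-frame 480×270 clip, threshold-monotonicity sweeps on
twenty 600-frame 96×54 replicates at noise sd 30, oracle-equivalence checks
on 500 random series up to 1,000 frames, and distractor/bleeding suites on
~2,000-frame clips. These sizes exercise every code path and invariant while
keeping a full verification run around a minute; the pipeline itself streams
frames and runs unchanged on multi-hour full-HD video.

## Known limitations

* The color model assumes standard drape colors and white-balanced
  illumination; a red-tinged drape or heavy white-out would need
  recalibrated thresholds.
* Auto-calibration needs the sampled frames to show all three color
  populations (see above); supplying a saved reference is the robust path
  for short or atypical clips.
* The reviewer model is perfect; an error-prone reviewer (missed vetoes,
  wrong rejections) is out of scope.
* Partial blood contamination without withdrawal, bleeding-severity
  scoring, and surgical-phase recognition are out of scope — phases enter
  only as annotation files.
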