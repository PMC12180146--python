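# Methods

This note documents the models, conventions and numerical choices behind
`escapekin`, and what the synthetic-data tests do and do not establish.

## Body model and input contract

A larva is seven keypoints (TS, S1, S2, T1–T4, head to tail) forming six
linked segments. Input tables use the DeepLabCut output dialect (three
header rows: scorer / bodyparts / coords; x, y, likelihood per bodypart),
mapped by keypoint name, calibrated by `px_per_mm` (typically 44–45) to
mm. Coordinates keep the image convention (y down); all angular
quantities are defined relative to body-internal references and the
rotation sign is re-standardized per trial, so axis handedness never
reaches the outputs. Missing keypoints are a hard error: curvature is a
sum over joints and is undefined with gaps, and interpolating tracking
failures would silently fabricate kinematics.

Quality gates per trial: (1) the larva must be stationary over the 10
pre-stimulus frames (max S2 excursion ≤ 0.05 mm — above the jitter floor
of a well-trained network, below any real movement); (2) no keypoint may
hold likelihood < 0.98 for ≥ 3 consecutive frames (sustained low
confidence marks erratic tracking; single-frame dips are tolerated);
(3) ≥ 60 ms of frames must remain after movement onset. Trials whose
birefringence phenotype contradicts their genotype (affected but not
−/−, or unaffected but −/−) are excluded from analysis sets.

## Angular kinematics

Tail joint angles use the *relative* (joint-angle) convention: tail1
against the trunk axis S1→S2, each further segment against its proximal
neighbour. The four relative angles telescope, so their sum — tail
curvature κ — equals the tail-tip orientation relative to the trunk; a
straight larva has κ = 0 at any heading, and rigid motions cancel
exactly. The alternative (all segments against the trunk axis) would
count distal bending four times over. Angles are unwrapped per joint over
time to survive ±180° crossings during tight C-starts; at jitter well
above the 64 µm regime the unwrap can accumulate drift on the short tail
segments — such trials fail segmentation and are reported as null rather
than silently analyzed.

Angle series are smoothed with LOESS (local linear fits, tricube
weights), span 0.10 of the series; instantaneous speed is smoothed at
span 0.7. LOESS reproduces constants and lines exactly and needs no
boundary padding. Angular velocity is the central finite difference of
smoothed κ (exact through quadratics), with first-order one-sided
differences at the two series ends.

**Onset.** Movement onset is the first post-stimulus frame whose
curvature exceeds the preceding frame by 2% and keeps growing. Applied
literally at κ ≈ 0 the rule is ill-posed, so two guards are added: a
curvature floor (0.5°) below which growth is ignored, and a confirmation
window (2 frames of continued growth) so single-frame blips cannot
trigger. The rule runs on *raw* curvature referenced to the pre-stimulus
baseline and passed through a 3-frame centered median. Raw, because the
span-0.10 LOESS smears the rise ~2 frames backward and would bias onset
early; baseline-referenced, because a static tracking offset otherwise
inflates the "preceding frame" term; median-filtered, because one-frame
tracking outliers should neither fake nor mask an onset. On noise-free
data the median of a monotone rise is the sample itself, so the detected
onset is exact.

## Linear kinematics

S2 stands in for the center of mass. Distance is the cumulative sum of
consecutive-frame S2 steps and displacement the magnitude of the vector
from the onset position, both on unfiltered coordinates. Speed is the
central difference of distance; velocity the central difference of
displacement; acceleration the central difference of velocity — so speed
≠ |velocity| whenever the path curves, by construction. Body length is
the six segment lengths summed and averaged over pre-movement frames; all
linear outputs are in BL, BL/s, BL/s².

## Stages, strokes, and the 31-variable catalog

After sign standardization (first major bend positive; an initial
opposite-signed bend with peak below 25% of the C-start peak is treated
as a counter-bend and ignored), the first curvature sign change past the
C-start peak ends stage 1, the second ends stage 2, and stage 3 runs to
onset + 60 ms. Strokes are delimited by successive extremes of smoothed
κ, found with a 2° prominence threshold (rejects noise ripples; plateau
ties resolve to the first frame). Stage 1's stroke spans onset → C-start
peak, stage 2's the C-start peak → power-stroke peak; stage 3 strokes
chain onward from the power-stroke peak, with a trailing partial stroke
flagged and excluded from per-stroke averages.

The catalog is 4 overall variables (60 ms distance, displacement, peak
smoothed speed, peak acceleration) plus, per stage, duration, distance,
displacement, average speed, exit speed (smoothed speed at stage end; at
60 ms for stage 3), max |ω|, and max acceleration (signed maximum within
the stage), plus stage-specific extras: stage 1 final tail curvature (κ
at the C-start peak), stage 2 curvature change (peak-to-peak of the
power stroke), and for stage 3 the number of complete strokes, average
distance per complete stroke, average stroke peak-to-peak amplitude, and
average stroke frequency (complete strokes ÷ summed complete-stroke
duration, in strokes/s; beat frequency is half this since two strokes
make one beat). That totals 31 variables, 27 of them stage-specific.
Stage durations partition the 60 ms window exactly and per-stage
distances sum to the overall distance, since all derive from one
unfiltered path. Latency (stimulus → onset) is carried as metadata, not
as a feature.

## Inference

Trials collapse to per-larva means (canonically 3 trials); a larva with
any null trial is flagged and excluded. The repeatability coefficient is
1.96·√2 ≈ 2.77 × the within-subject SD from the one-way (larva-as-factor)
variance decomposition, pooling within-larva variances weighted by
(trials − 1); larvae with one trial carry no within-subject information
and are dropped. It bounds the absolute difference of two repeated
measurements at the 95% level.

Group contrasts use the bias-corrected-and-accelerated bootstrap (default
5000 resamples, 99% CI), resampling larvae independently within each
group — never trials, which are not the analysis unit. The bias
correction z₀ is the normal quantile of the (mid-ranked) fraction of the
bootstrap distribution below the point estimate; the acceleration is the
jackknife skewness over leave-one-out estimates from both groups.
Hedges' g uses the (n−1)-weighted pooled SD and the small-sample factor
J = 1 − 3/(4(n_a+n_b) − 9). Power calculations use the noncentral-*t*
distribution for two-sample and paired designs with the standardized
effect d = relative effect × mean / SD. No multiple-testing correction is
applied: results are per-variable 99% intervals, reported as such.

## Classification

Mutants (−/−) are contrasted against pooled wild-types (+/+ and +/−).
The random forest (500 trees, mtry = ⌊√p⌋) trains each tree on a
bootstrap sample and scores out-of-bag — the OOB votes give the error
rate, confusion matrix and AUROC; importance is mean GINI decrease. The
linear SVM z-scores features on the training split, tunes C over 50
log-spaced values in (0.01, 5] (C = 0 removes the margin penalty entirely
and is excluded as ill-posed) by stratified tenfold CV on a 70% split,
and reports the held-out 30% confusion matrix and decision-value AUROC.
Top-k importance lists intersect across strain × model combinations with
ties broken by catalog order. PCA summaries use the correlation matrix
(unit-scaled variables; constant columns dropped with a warning).

## Twitch analysis

Baseline is the pre-stimulus mean force; onset the first post-stimulus
sample above baseline + 3 SD of the baseline (threshold crossing
interpolated between samples, so contraction time does not quantize with
the sample rate); contraction time runs from force onset (stimulus-
referenced optionally) to the baseline-subtracted peak; half-relaxation
time to the linearly interpolated 50% decay crossing; the rate metrics
are the extrema of the central-difference derivative of force smoothed by
a fractional-weight boxcar spanning exactly 1 ms at any sample rate.

## The simulator

`simulate` builds a post-stimulus curvature waveform — zeros through a
~7 ms latency, an optional counter-bend, a half-cosine rise to +A1 over
d1, a cosine swing to −A2 over d2, then a sinusoid at the stroke
frequency f with amplitude A3 (Gaussian-bridged from A2 so the join is
C¹; optional per-stroke decay) — and renders keypoints by inverting the
analysis model: κ is split over the four joints with fixed weights
(0.1/0.2/0.3/0.4), the heading turns during stage 1 in proportion to A1,
and the COM advances at v = c·|ω| (propulsion gain c in BL per degree of
integrated |ω|). This proxy contains no hydrodynamics; it preserves
exactly the coupling the pipeline must detect — a slower tail moves the
larva less. Isotropic Gaussian jitter (SD 64 µm, the accuracy scale of a
well-trained pose network) is added per keypoint; while the larva has not
yet moved the jitter is frozen across frames, because a deterministic
network viewing a static scene returns the same estimate each frame.
Closed-form stage-boundary times are exposed
(`true_stage_boundaries`): the first sign change falls *inside* the power
stroke at d1 + (d2/π)·arccos((A2−A1)/(A1+A2)), the second a half stroke
into the burst.

Wild-type defaults (A1 = 120°, d1 = 9 ms, A2 = 110°, d2 = 8 ms, A3 = 80°,
f = 140 strokes/s, c = 0.0023 BL/deg) give ~3.5 BL in 60 ms with 5–6
burst strokes — a typical vigorous escape. The dystrophic preset slows
time rather than shrinking excursions: durations ÷ 0.6, stroke frequency
× 0.6, amplitudes × 0.95, propulsion gain unchanged, so angular
velocities fall ~40% while peak-to-peak amplitude is near-preserved and
the distance deficit emerges mechanistically. These presets are simulator
conventions encoding the qualitative phenotype, not measured values.
Between-larva variation is log-normal (CV 0.08) on amplitudes, durations
and frequency — a modelling convention, as the true joint distribution of
larval parameters is unknown. All draws flow from one seed through
`SeedSequence` spawning; cohorts are bit-reproducible.

## What the synthetic tests show — and what they do not

Round-trip tests (render → track → analyze) verify the geometry and
bookkeeping exactly, because the renderer inverts the body model by
construction. Parameter-recovery tests verify stage boundaries against
the closed forms and stroke frequency against planted values in the
wild-type burst regime. Two measurement limits are documented rather
than hidden: (1) LOESS at span 0.10 attenuates 7 ms strokes well beyond
5%, so stroke-amplitude recovery is checked against an independent
smoothed-waveform oracle (brute-force extreme scan on the analytic
series), not against raw construction amplitudes — on real data the same
attenuation applies uniformly across groups, leaving contrasts
interpretable but absolute amplitudes conservative; (2) per-trial stroke
frequency resolves to ~(localization error)/(burst span), so a slowed
tail leaving ~2 strokes in the window cannot be timed to 5% at 1 kHz.
None of this establishes accuracy on real video: the simulator has no
hydrodynamics, no 3-D pitch, no habituation, no occlusion-driven
likelihood drops, and its noise is isotropic and Gaussian where real
pose error is pose-dependent.

## Problem sizes

The default test suite and the acceptance script run on one CPU in a few
minutes total: rendered cohorts of 28–60 trials, calibrated statistical
cohorts of 50 larvae per class, 500-replicate coverage simulations with
2000 bootstrap resamples, and 48-preparation twitch cohorts — sizes
chosen to keep Monte-Carlo error comfortably inside each test's
tolerance.
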