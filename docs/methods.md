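# Methods

This note documents the models, conventions and open design choices behind
`penkit`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and the synthetic-data generator

The device model is a pen recording tri-axial linear acceleration (m/s²),
tri-axial angular velocity (deg/s) and tip force (arbitrary units, ≥ 0) at a
uniform 50 Hz, plus a per-sample word-type label track used only in the
dictation task. No published raw-signal distributions exist for this kind of
device, so the generator's channel model is an explicit artifact choice,
built so that every indicator has a controllable generator-side counterpart
rather than for waveform realism. The written trace is deliberately not
modelled: none of the indicators uses it.

A recording is rendered from a schedule of alternating on-sheet strokes and
in-air gaps:

* **Stroke durations** are Gaussian around `stroke_dur_mean` (SD 20%,
  floored at 0.1 s). **Gap durations** come from two well-separated regimes:
  with probability `pause_prob` a pause, uniform on 2.2–6 s; otherwise a
  uniform 0.1–1.5 s rescaled so its mean equals `gap_dur_mean` and capped at
  1.9 s. The two regimes never straddle the 2 s pause threshold, so the
  threshold's boundary behaviour is exercised only by explicitly scripted
  tests.
* **Force** is `force_level` with 4% smoothed jitter during strokes, near
  zero in the air, plus occasional Gaussian overshoot spikes scaled by
  `force_overshoot_scale`.
* **Angular velocity** is a band-limited oscillation at `stroke_rate`
  (default 3 Hz — the grapheme-generation rhythm) enveloped by the stroke
  mask, plus a tremor component at `tremor_freq` (default 8 Hz) whose
  relative power is `1 − smoothness`, plus an always-on tremor floor of
  amplitude `tremor_amp`. `SubjectParams.stroke_rate` is the kinematic
  oscillation frequency; the stroke/gap schedule is governed by the duration
  fields.
* **Acceleration** is gravity (9.81 m/s², pen axis = device z) seen by a pen
  at angle `tilt_mean` to the vertical with slow (0.1–0.8 Hz) multiplicative
  variation of coefficient `tilt_cv`, plus 2.5–5 Hz movement transients and
  the same tremor structure during strokes.

The dictation task renders the fixed 15-item script (7 regular, 3
irregular, 5 made-up Italian words, in that order) as one labelled block
per word — roughly one stroke per two letters — separated by unlabelled
1–1.8 s dictation gaps. Word-type tempo multipliers act on intra-word in-air
durations (default: irregular words 1.5× slower in the air, the surface
dysgraphia signature) and optionally on stroke durations.

**Cohorts** are drawn hierarchically. For each parameter with base value
`b`: subject value = `b + effect·σ_b·1[MCI] + σ_b·z`, session value adds
`σ_w·z′`, with `σ_b = sigma_between·b` and `σ_w = sigma_within·b`
(scalars are relative SDs; dicts give per-field values). Effects are
standardized shifts in between-subject SD units; the default MCI preset
slows tempo, raises hesitation (`gap_dur_mean`, `pause_prob`), lowers
`smoothness` and raises `tilt_cv`. By construction the true test-retest ICC
of any parameter is `σ_b²/(σ_b²+σ_w²)`, which the reliability stage must
recover. Block-letter writers get deterministic prior shifts (20% shorter
strokes, 20% longer gaps); the channel model itself is allograph-agnostic —
enough to exercise the per-allograph analysis split, not a claim about real
allographs. Defaults (`sigma_between=0.15`, `sigma_within=0.05`,
allograph mix ≈ 62/33/5 cursive/block/other, 45+45 subjects) mirror a
cohort in which most indicators are reliable and group effects are
detectable at realistic sizes.

What the generator does **not** emulate: letterforms and trace geometry,
age/education covariates, fatigue or learning across sessions, device
calibration drift, and heavy-tailed force artifacts. A passing suite
therefore shows the *pipeline* is correct and calibrated under the stated
statistical structure, not that real MCI handwriting will behave this way.

## Segmentation

Contact is inferred from force with hysteresis: pen-down above `θ_on`,
pen-up below `θ_off = 0.5·θ_on`; runs shorter than 0.04 s (2 samples) are
merged into their neighbour, shortest first. Because force is in arbitrary
units, the default `θ_on` is 5% of the recording's force range; it should be
set absolutely when the device calibration is known. Intervals are 0-based,
half-open, in samples; strokes and airs exactly partition the recording.
Execution time runs from the first to the last recorded sample (leading and
trailing air count); the alternative clock (first pen-down) is a one-line
change and flagged for sensitivity analysis. Pauses are in-air intervals
*strictly* longer than 2 s. Hysteresis makes contact detection robust to
force jitter at 50 Hz but only approximately time-symmetric: reversal
invariance is exact on clean force edges and holds to ~1% under jitter.

## Indicators

Thirty-two indicators across six domains (temporal ×10, fluency ×6, force
×4, tilt ×3, high-frequency time ×1, high-frequency frequency ×8). The
numerically load-bearing conventions:

* Tri-axial channels enter as their Euclidean norm, except the explicitly
  "dominant-axis" spectral indicators (the axis with greatest total-band
  power). A consequence worth knowing: a zero-mean tone on a single axis is
  full-wave rectified by the norm (its fundamental doubles); oscillatory
  content rides on the gravity / movement offset in practice.
* **LDLJ** per stroke on the norm `s(t)`:
  `−ln((T³/s_peak²)·(1/T)∫ṡ²dt)` with central-difference derivatives and
  trapezoidal integration; mean over strokes of ≥ 4 samples. Amplitude
  scaling cancels via `s_peak`. Because the norm of an
  acceleration/angular-velocity signal carries a large offset, values can be
  positive; only the ordering (more negative = less smooth) is interpreted.
* **SPARC** per stroke of ≥ 8 samples: 4× zero-padded magnitude spectrum,
  max-normalized; adaptive cutoff = largest frequency ≤ 20 Hz with
  normalized magnitude ≥ 0.05; minus the arc length over [0, cutoff] with
  frequency normalized by the cutoff.
* Smoothness metrics are computed per stroke and averaged: they are defined
  for discrete movements, and concatenating across in-air gaps would corrupt
  the spectrum. (An open interpretation; flagged here.)
* **Oscillation counts (NC)** use alternating extrema (prominence ≥ 1% of
  the stroke's range, same-type neighbours collapsed to the more extreme),
  chosen over zero-crossings because the paired indicator is the mean
  absolute difference between *consecutive extrema*. Counts are per second
  of on-sheet time. Closed-form expectations (e.g. 4 extrema/s for a 2 Hz
  sine) are met up to sampling of the extrema (≲ 0.4% at 50 Hz).
* **Force** indicators use on-sheet samples only; overshoot = max − median.
* **Tilt** = angle between the 2 Hz zero-phase low-pass-filtered
  acceleration vector and the device z axis, folded to [0°, 90°] so either
  gravity alignment reads 0°. `tilt_cv` is reported missing below a 1° mean
  (ratio instability).
* **ApEn** is the classical definition with self-matches, `m=2`,
  `r=0.2·SD` — the field-standard parameterization — on the whole-task
  acceleration norm (≥ 50 samples).
* **Spectra** use 2.56 s Hann windows (128 samples) with 50% overlap; the
  total band is 0.5–25 Hz (the 0.5 Hz floor keeps DC/drift out of every
  normalization, with mean-detrended windows). "Median relative power" is
  the median across sliding windows of band power / total-band power —
  the windowing is an interpretation, as is reading "median bandwidth" as
  the 25%→75% cumulative-power width (an interval holding 50% of total
  power). The 68% peak bandwidth grows symmetrically in bins around the PSD
  peak until 68% of total band power is covered.
* Missing values are NaN and propagate through all downstream statistics by
  pairwise deletion; degenerate content (all-air recordings, constant
  signals) yields missing values, never exceptions.

## Reliability

Per indicator: (1) paired test on test−retest differences — paired t if the
differences pass a Lilliefors gate at 5%, Wilcoxon signed-rank otherwise;
rejection excludes the indicator (a systematic session shift can coexist
with high correlation). (2) Otherwise ICC(A,1) (two-way random effects,
absolute agreement, single measurement; significance from
`F = MS_rows/MS_error`) when the pooled values pass the gate, else
Kendall's W for two sessions ranking the subjects, mid-rank ties, tie
correction and chi-square significance. Two separate gates are used — on
the differences for the paired test, on the pooled values for the
coefficient — because a single "normality" flag is ambiguous between the
two roles. (3) Categories: not reliable (ICC < 0.5 or W < 0.2), fair
(0.2 ≤ W < 0.4, W only), moderate (0.5 ≤ ICC < 0.75 or 0.4 ≤ W < 0.6), good
(0.75 ≤ ICC < 0.9 or 0.6 ≤ W < 0.8), optimal (ICC ≥ 0.9 or W ≥ 0.8);
negative coefficients are clipped at 0 for categorization. CV-type
indicators are excluded from the analysis; subjects who switched allograph
between sessions are dropped; no multiplicity correction is applied (raw p
at 5%). Fewer than 8 complete pairs abstains (stratum skipped).

ICC(A,1) is computed directly from the two-way ANOVA mean squares for speed
in Monte-Carlo suites; the test suite cross-checks it against an independent
implementation to 1e-10.

## Correlations and word-type contrasts

Correlations are Pearson when *both* variables pass the normality gate
(a bivariate reading of the gate), Spearman otherwise, with strength bands
weak/moderate/strong/very strong at 0.2/0.4/0.6/0.8. Clinical scores are
ordinal in practice, so the gate routes them to Spearman almost always.
Error counts on irregular dictation words are correlated against indicators
extracted from irregular words only, when that table is supplied.

The word-type contrast averages per-word indicators within type (7 regular,
3 irregular, 5 made-up words — so type-mean noise scales as `σ/√n_words`),
then runs a one-way repeated-measures ANOVA (all three series normal;
sphericity uncorrected, Greenhouse–Geisser epsilon reported
informationally) or a Friedman test. Only on rejection, three paired
post-hocs (R−I, MU−I, R−MU) follow the omnibus family — paired t with a
t-based 95% CI, or signed-rank with a Hodges–Lehmann estimate and a
signed-rank-order-statistic interval — with Bonferroni ×3 capped at 1.

## Classification

Rows are (subject, session) executions of the list and/or text task,
optionally filtered by allograph; features are handwriting indicators only
(never age or clinical scores). The combined dataset requires both tasks
per row and suffixes features `_L`/`_T`. A greedy in-column-order filter
removes any indicator correlating above |r| = 0.9 with an already-retained
one; it is applied at dataset assembly and re-fitted inside each repeat's
training split, so no choice anywhere in the pipeline sees validation or
test data (a `resample_validation` compatibility flag reproduces the looser
variant that also resamples the validation split, with a leakage warning).

Evaluation is Monte-Carlo cross-validation: the stated 70/15/15 ratios are
only consistent with repeated seeded stratified random splits, so that is
what "10-fold stratified repeated CV" is implemented as. Per repeat, a
30-draw randomized search samples (model, sampler, optional ANOVA-F select-K
with K ∈ {10…50}, hyperparameters), fits on the (resampled) training split,
selects by validation F1 with a deterministic tie-break — fewer features,
then lexicographically smaller configuration, then first seen — refits the
winner on train+validation and scores the test split on accuracy, recall,
precision, F1 and PR-AUC, averaged over repeats. Missing values are imputed
with training medians. The model zoo: RBF SVC (standardized), random
forest, AdaBoost, gradient boosting, and three histogram/ordered-style
boosters (XGBoost, LightGBM, sklearn's HistGradientBoosting). Search spaces
are compact documented defaults per family (C and gamma log-uniform;
50–200 estimators; depths 2–4 for boosters). The samplers are own
implementations over sklearn nearest-neighbour machinery: random
undersampling, NearMiss-1, edited nearest neighbours, SMOTE,
Borderline-SMOTE, SVM-SMOTE (minority support vectors as seeds) and ADASYN.
Everything derives from the master seed; identical inputs give identical
reports.

**Explanation.** Shapley attributions are estimated by permutation sampling
against a single background row (the training medians): for each sampled
feature ordering, features flip from background to sample value and the
score deltas accumulate. Because each ordering telescopes, attributions sum
exactly to `f(x) − f(background)` per sample. Indicators are ranked by mean
|attribution|; the reported direction is the sign of the association
between feature value and attribution (+ = high values push toward MCI).
Misclassified test samples are profiled on the top-5 indicators, min-max
normalized over the pooled dataset and clipped to [0, 1], against group
medians and interquartile bands; radar plots place the most relevant
indicator at the top and proceed counterclockwise.

## Problem sizes and calibration checks

The acceptance suites run at desk scale, chosen once: 200 scripted
segmentation profiles; 500×n=200 ICC recovery (true 0.8, tolerance ±0.03);
200×n=45 paired-gate runs; 1000-run type-I checks for the correlation and
omnibus stages (5% ± 2%); 200×n=30 word-type power runs; classification
checks on 31-indicator matrices with 60+60 rows (planted standardized
effects of 1.5 on 10 indicators), 10 repeats with an SVC + random-forest
search of 10–30 draws. Monte-Carlo contrast and power checks operate on the
statistical models the pipeline stages consume (paired per-type series;
indicator matrices); signal-level integration from cohort simulation
through extraction to statistics is covered separately at smaller n.

## Known limitations

* The generator's channel model is stylized; absolute indicator values
  (e.g. LDLJ offsets, band powers) are meaningful only comparatively.
* Indicator catalogues for this class of device run far larger than what is
  implemented here: this package provides the 32 indicators documented
  above and leaves the remainder as an extension point
  (`INDICATOR_DOMAINS` is the single registry to extend).
* Chance-level behaviour of an F1-optimizing selection is mildly above 0.5
  on balanced data (degenerate all-positive classifiers achieve F1 ≈ 0.67);
  the pipeline's observed chance F1 lands near 0.55 and should be read
  against that baseline.
* Kendall W significance uses the chi-square approximation, which is crude
  below ~10 subjects; the pipeline already abstains below 8 pairs.
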