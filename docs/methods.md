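# Methods

This note records the model the package implements, the conventions that
were genuinely open, and how each was fixed.

## The stress-profile session

A session is defined by a `ProtocolDefinition`: an ordered list of stages
(label, role ∈ {baseline, stressor, recovery}, duration in seconds) plus
the sampling rate. The default protocol has nine 2-minute stages at
256 Hz — baseline first, then four stressors alternating with four
recoveries — for 276,480 samples per channel. Recordings carry three
channels in canonical order: blood volume pulse (%), abdominal
respiration (%), skin conductance (µS).

Stage segmentation assigns stage *k* the next round(d·fs) rows.
Intervals are 0-based and half-open, so they concatenate without
ambiguity. When the offset trim removes leading rows, the whole deficit
is charged to stage 1: stage clocks are wall-clock anchored in the lab,
so the baseline simply loses its first half second and every later stage
keeps its position in time.

## Preprocessing

1. **Offset trim** (default 0.5 s): biofeedback amplifiers show a
   settling transient at the start of acquisition.
2. **Median filter**: window `w = round(length / (4 · fs))`, adjusted to
   the nearest odd integer with ties broken downward and floored at 3.
   At the default session length this gives w = 269 (~1.05 s at 256 Hz),
   wide enough to reject multi-sample motion transients, narrow enough
   (w ≪ stage length) to leave stage structure untouched. The window
   rule is exposed through `kernel_fraction` so other readings of the
   length/rate trade-off can be tested. The kernel is derived from the
   whole post-trim session length, not per stage, so all stages are
   filtered identically.
3. **Standard scaling** per channel, z = (x − a)/s with the population
   (divisor N) standard deviation, matching the common standard-scaler
   convention; `ddof=1` switches to the sample convention. The
   parameters are returned so the transform is invertible.

**Edge convention.** The median filter truncates its window symmetrically
at the recording boundaries (effective half-width min(k, i, n−1−i))
rather than padding: no data is fabricated beyond the recording ends.
The cost is that the outermost samples are filtered with shorter windows
— the boundary sample itself passes through unchanged — so an impulse
landing in the first or last half-window can survive. With w ≪ n this
affects ~0.1 % of samples and no stage centroid measurably; the
artifact-suppression guarantee applies to the full-window interior.

**Order of operations** is trim → filter → scale, so the settling
transient never contaminates either the kernel-length computation or the
scaling parameters.

## The index

Standardized samples are rotated by full-rank PCA (scikit-learn, exact
SVD). Since every component is retained, the rotation is orthogonal and
preserves Euclidean distances; RSI computed on scores equals RSI
computed on the standardized channels to 1e−6 (asserted as a test). The
rotation is kept for decorrelation and plotting, not reduction. PCA,
like scaling, is fit per subject per session: each session is measured
against its own calibration stage, never pooled across subjects or
across pre/post.

With stage centroids c₁…c_K (arithmetic means of each stage's rows),

* ΔR = ‖c_{K−1} − c_K‖₂ — movement between the last two stages,
* ΔS = max_{k≥2} ‖c₁ − c_k‖₂ — maximal excursion from baseline,
* RSI = ΔR/ΔS.

RSI is not clipped by default: ΔR can exceed ΔS when the final recovery
overshoots past the baseline relative to the penultimate stage. Cohorts
reported with values capped at exactly 1.000 suggest some analysts clip;
`clip=True` reproduces that, and the flag is off by default so the raw
geometry is visible.

Degenerate inputs: a session whose centroids all coincide with the
baseline has ΔS = 0 and is rejected as degenerate rather than returning
0/0. A constant channel is rejected at scaling (and again at the PCA if
scaling was disabled); exactly collinear channels are accepted and yield
a zero-variance trailing component, which is harmless under an
orthogonal transform.

## Cohort statistics and their calibration

Three conventions are underdetermined in principle; each was fixed by
calibrating against the bundled 38-subject reference cohort and is
exposed as an option.

* **Quartiles** (`quartile_method`): the inclusive-median rule (Tukey
  hinges — each half of the sorted sample, sharing the median position
  for odd halves) reproduces the reference five-number summaries at the
  printed 2-decimal precision; linear interpolation does not (it puts
  the post-test upper quartile at 0.40 instead of 0.41). Default
  `"inclusive"`; `"exclusive"` and `"linear"` are available. Whiskers
  are Tukey: the most extreme data points within 1.5·IQR of the
  quartiles; points beyond are listed as outliers.
* **Wilcoxon sign orientation**: R⁺ collects ranks of pairs with
  pre > post. This is what reproduces the reference rank sums
  (R⁺ = 234 < R⁻ = 507 in a cohort that mostly improved); the opposite
  orientation merely swaps the labels and leaves the p-value unchanged.
  Zero differences are dropped; tied absolute differences share average
  ranks.
* **Wilcoxon p-value** (`wilcoxon_method`): the large-sample normal
  approximation without continuity correction is the default; the
  continuity-corrected variant and an exact enumeration (dynamic
  programming over the 2^m sign patterns; requires untied absolute
  differences) are available. On the reference cohort the default and
  the exact method agree to 4 decimals.

Welch's *t* is oriented pre − post with Welch–Satterthwaite degrees of
freedom; p-values use the raw non-integer df. The df is also reported
rounded to the nearest integer (`df_int`), which is how spreadsheet
t-test tools print it, and the α = 0.05 critical values are computed at
that integer df to mirror the same output. Sample (divisor n−1)
variances throughout the cohort battery.

The improvement fraction counts strictly positive post − pre
differences; zeros count as not improved.

The bundled reference table stores each subject's RSI at the 3-decimal
precision it was reported with. Statistics recomputed from it therefore
differ from values computed on unrounded data in the 3rd–4th significant
figure (e.g. t = −2.3018 here); the package's tests bound these
comparisons by propagating the ±0.0005 quantization, and the table's
own difference column is always recomputed rather than trusted.

## The synthetic-data generator

The generator models what the RSI actually measures — stage-mean
geometry — rather than waveform morphology. Per channel, each stage has
a level: baseline at the configured resting values (defaults BVP 36 %,
respiration 33 %, conductance 4.4 µS, typical of resting biofeedback
readings); stressors displaced by the reactivity vector (−2 %, +2.5 %,
+1.5 µS — conductance and breathing rise under sympathetic arousal, BVP
falls); recoveries retaining (1 − recovery_fraction) of the preceding
stressor's excursion (default 0.6 relieved). The final stage's level is
the convex combination (1 − ρ)·c_{K−1} + ρ·baseline, so the ground-truth
noise-free RSI equals ρ exactly: ρ is the quantity the pipeline should
recover.

Superposed on the levels: a cardiac-band sinusoid on BVP (1.2 Hz,
amplitude 1.5), a respiratory-band sinusoid on respiration (0.25 Hz,
amplitude 1.2), white noise per channel (SD 0.5 / 0.4 / 0.05), an AR(1)
drift on skin conductance (φ = 0.98, innovation SD 0.02 — slow tonic
electrodermal wander), and Poisson-timed impulse artifacts (default
1/min, ±30 channel units, 5 samples long — electrode pops and motion
transients, the median filter's reason to exist). All randomness flows
from a single seed through one named generator; cohort generation spawns
per-subject seeds from the master seed, so recordings are bit-identical
across runs.

What the generator does **not** emulate: real pulse-waveform morphology
and beat-to-beat variability, breathing irregularity, motion baseline
shifts, inter-channel physiological coupling beyond the shared stage
structure, and individual differences in reactivity shape. Passing
tests therefore demonstrate that the pipeline recovers cluster-geometry
ground truth under realistic noise and artifacts — not that the RSI is a
valid construct for real physiology, which only recorded data can show.

## Problem sizes in tests and the acceptance script

RSI depends only on stage-centroid geometry, and centroid Monte Carlo
error shrinks with the per-stage sample count, so simulations use the
standard 9 × 120 s protocol at reduced sampling rates: 32 Hz (3,840
samples/stage) for single-cohort checks and 8 Hz for the 200-replicate
null calibration, with full 256 Hz covered by single-subject tests. At
32 Hz the pipeline RSI matches ρ to ±0.01 at default noise, so nothing
about the checks changes at higher rates. The null calibration runs
10-subject cohorts per replicate; the observed type-I error rate at
α = 0.05 is 0.05.

## Known limitations

* The index needs ΔS meaningfully larger than centroid noise; very flat
  sessions (no physiological reaction to any stressor) make RSI
  unstable, and the truly degenerate case raises an error.
* Boundary samples are lightly filtered (see the edge convention above).
* No HRV derivation from the BVP waveform: the pipeline consumes the
  three raw channels. `fit_full_pca` and the centroid machinery accept
  matrices of any width, so a derived HRV column can be appended
  upstream if available.
* The reader accepts only delimited text (CSV/TSV); no EDF/BDF or
  proprietary biofeedback formats.
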