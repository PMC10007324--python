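# stressprofile

Quantifying autonomic recovery from psychological stress with the
**Resilience to Stress Index (RSI)**.

## The problem

In a psychophysiological *stress profile*, a subject wears non-invasive
sensors — blood volume pulse (BVP, %), abdominal respiration (%), skin
conductance (µS) — through an 18-minute session of nine 2-minute stages
sampled at 256 Hz: a resting **baseline**, then four psychological
**stressors** (Stroop, mental arithmetic, auditory, emotional recall)
alternating with quiet **recovery** periods. Stress pushes physiology
away from the subject's own baseline (conductance and breathing rise,
pulse amplitude falls); resilient subjects drift back during recoveries.

After per-channel cleaning (offset trim, running-median filter,
standard scaling *z* = (*x* − *a*)/*s*) the samples of each stage form a
cluster; with stage centroids **c**₁ … **c**₉ computed in full-rank PCA
space (an orthogonal, distance-preserving rotation), the index is

```
RSI = ΔR / ΔS,   ΔR = ‖c₈ − c₉‖₂,   ΔS = max_{k≥2} ‖c₁ − c_k‖₂
```

ΔR is how far physiology moved between the final stressor and the final
recovery; ΔS is the maximal excursion from baseline anywhere in the
session. RSI ≈ 1 means the subject returned all the way from their worst
excursion to their own calibration state; RSI ≈ 0 means the final
recovery changed nothing.

The package is aimed at researchers running pre/post intervention
studies: it computes per-session RSI values from raw delimited-text
recordings, evaluates a paired cohort (Welch's unequal-variance *t*-test,
Wilcoxon signed-rank test, Tukey boxplot summaries, improvement
fraction), and ships a seeded synthetic-signal generator whose
ground-truth recovery parameter ρ equals the noise-free RSI by
construction, so the entire pipeline is testable without any recorded
data.

## Worked example

The package bundles a reference cohort: pre/post RSI values for the 38
students of a published biofeedback-assisted mindfulness study. The
`demo` subcommand runs the whole statistical battery on it:

```
$ stressprofile demo --out demo_out
Cohort report (n = 38 paired subjects)

Boxplot values
          LowerWhisk  Q1      Median  Q3      UpperWhisk
Pre-test  0.12      0.17    0.22    0.30    0.39
Post-test 0.11      0.20    0.28    0.41    0.67

Improved subjects: 65.8%

Welch's t-test (two-sample, unequal variances)
  Mean      0.24697368  0.32121053
  Variance  0.0092535  0.03027195
  Observations  38  38
  df  58  (raw 57.6872)
  t Stat  -2.3018283
  P(T<=t) one-tail  0.0124875
  t Critical one-tail  1.67155276
  P(T<=t) two-tail  0.024975
  t Critical two-tail  2.00171748

Wilcoxon signed-rank test
  R+ 234  R- 507  (n effective 38)
  p-value 0.04775  [normal_approx]
```

Reading the output: about two thirds of subjects improved; the mean RSI
rose from 0.247 to 0.321; Welch's *t* = −2.30 (*p* = 0.025) and the
signed-rank test (*p* = 0.048) both reject equality of pre and post at
α = 0.05 — the intervention moved the cohort toward better autonomic
recovery. The post-test upper whisker (0.67) sits far above the
pre-test one (0.39).

Synthetic recordings round-trip through the same pipeline:

```
$ stressprofile simulate --out sim --seed 7 --n-subjects 2
wrote 4 recordings and ground truth to sim
$ stressprofile compute sim --protocol sim/protocol.yaml --out rsi
sim001_post: RSI = 0.5249
sim001_pre: RSI = 0.1981
sim002_post: RSI = 0.9072
sim002_pre: RSI = 0.5089
wrote 2-row cohort table to rsi/cohort.csv
```

Compare with `sim/ground_truth.csv` (ρ values 0.21/0.53 and 0.52/0.92):
the recovered RSI tracks the generating recovery parameter to within a
few hundredths even at the default noise level.

The same operations are available as a library — see
`stressprofile.session_rsi`, `stressprofile.cohort_report` and
`stressprofile.simulate_cohort`.

## Layout

| module | contents |
| --- | --- |
| `stressprofile.protocol` | protocol/recording/cohort containers, I/O, stage segmentation |
| `stressprofile.preprocess` | offset trim, median filter (window = length/(4·fs)), standard scaler |
| `stressprofile.rsi` | full-rank PCA, stage centroids, RSI |
| `stressprofile.cohort` | descriptives, boxplots, Welch *t*, Wilcoxon signed-rank, report |
| `stressprofile.simulate` | seeded subject/cohort generators with ground-truth ρ |
| `stressprofile.cli` | `stressprofile compute / cohort / simulate / demo` |

Details of the model, conventions and their calibration are in
[docs/methods.md](docs/methods.md).
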