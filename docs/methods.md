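# Methods

`asppr` re-implements a patient-specific advance seizure prediction
pipeline for multi-channel intracranial EEG. The core idea is *pre-ictal
relabeling*: instead of asking "is a seizure imminent?", a family of
models is trained, one per horizon N ∈ {0, …, 20} minutes, each asked
"will seizure onset occur between N and N+5 minutes from now?". Each
horizon gets its own dataset, built from the baseline (t = 0) dataset by
moving the pre-ictal label window N minutes earlier.

## Instance model and labeling

EEG is consumed as one-hour, 6-channel "ictal files" sampled at 256 Hz,
each straddling a single seizure (~180 s). The signal is converted into
one feature-vector instance per 5-second tick, starting at t = 5 s, with
every feature computed from a window *ending at* the tick. One hour
yields 720 instances.

Each instance carries one of four states. With seizure onset at `on` and
offset at `off` (seconds), the instance at time t is

- **ictal** if t ∈ (on, off],
- **pre-ictal** if t ∈ (on − 300, on],
- **post-ictal** if t ∈ (off, off + 300],
- **inter-ictal** otherwise.

Half-open windows with the tick that ends exactly at onset counted as the
last pre-ictal instance keep the canonical file at exactly 60 / 36 / 60 /
564 instances (frequencies 0.08333 / 0.05 / 0.08333 / 0.7833). Seizures
closer than 300 s to the file start get a truncated pre-ictal window and
a warning rather than an error. When several seizures' windows overlap,
precedence is ictal > pre-ictal > post-ictal > inter-ictal (an extension:
source files contain one seizure each).

Horizon-N relabeling removes the instances in (on − 60N, on] and labels
those in (on − 60(N+5), on − 60N] pre-ictal. `removed_count` is 12N per
seizure; `relabeled_count` counts actual inter-ictal → pre-ictal changes,
i.e. 12·min(N, 5). Removal and relabeling never touch the same instance,
and ictal/post-ictal instances are never removed.

## Features (34 per channel, 204 total)

Windows: SE = 1280 samples (5 s), STE = 2304 (9 s), LTE = 46080 (180 s).
Ticks earlier than a full window use a growing window over all available
samples, so the matrix is dense from the first tick; this is the minimal
reading consistent with exporting from t = 5 s onward.

- **Signal energy** (SE/STE/LTE): mean squared amplitude over the window.
- **Accumulated energy**: running sum of the SE series plus a per-file
  random offset drawn once as U(0, 10 × median SE) from the extraction
  seed — the offset models the unknown energy accumulated before the
  file starts, and is shared across channels.
- **DWT band energies** (4 bands × {STE, LTE}): db4 wavelet, level-4
  decomposition *per window*. A level-4 dyadic split at 256 Hz yields
  sub-bands 0–8 (A4), 8–16 (D4), 16–32 (D3), 32–64 (D2), 64–128 Hz (D1);
  the nominal band edges 0–12.5/12.5–25/25–50/50–100 Hz cannot be
  realized dyadically at this rate, so A4+D4 are merged into the lowest
  reported band and D3/D2/D1 map to the remaining three. Per-window
  decomposition (rather than one whole-record transform) keeps every
  windowed feature exactly local to its window. The Daubechies order
  (db4) is the conventional EEG default.
- **Moments** (mean, skewness, kurtosis × {STE, LTE}): computed from
  cumulative power sums; kurtosis is the plain standardized fourth
  moment (3 for a Gaussian). Zero-variance windows return 0 with a
  degenerate flag instead of NaN so the matrix stays dense.
- **Spectral band power** (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–48 Hz
  × {STE, LTE}): integrated one-sided Hann-tapered periodogram over
  [f_lo, f_hi). The periodogram was chosen over Welch averaging because
  it has a simple closed-form behaviour on the test signals.
- **Spectral edge frequency** (SEF-50, SEF-90 × {STE, LTE}): smallest F
  with X% of the 0.5 Hz–Nyquist power below F; zero-power windows return
  0.5 Hz flagged.
- **Maximal Lyapunov exponent** (5-s window): Rosenstein-style — delay
  embedding, nearest neighbour outside a Theiler window, least-squares
  slope of the mean log divergence over forward steps, in nats per
  sample step. Neighbour search uses a float32 distance matrix; the
  tracked divergence distances are recomputed in float64 because
  catastrophic cancellation at small separations otherwise biases the
  slope upward (measured on the r=4 logistic map: float32 gave ≈1.2,
  float64 recovers ln 2 ≈ 0.693).
- **Correlation dimension** (5-s window): Grassberger–Procaccia — slope
  of log C(r) vs log r over radii log-spaced in [σ/100, σ], using only
  radii with ≥ 10 Theiler-separated pairs; degenerate windows return 0
  flagged.

Defaults for the nonlinear features (embedding dimension 10, delay 4,
Theiler window 20, 10 radii, 10 divergence steps) are stable at
1280-sample windows and all overridable via `FeatureConfig`. The two
nonlinear estimators share one embedded distance matrix per window; this
plus batched-by-length periodograms keeps a full one-hour file at
roughly a minute of extraction on one CPU.

## Feature selection

Multi-class ReliefF with Manhattan distance on min-max-scaled features;
each miss class contributes with weight P(class)/(1 − P(class of the
sampled instance)). Defaults k = 10 neighbours, m = min(n, 1000) sampled
instances (the source procedure prints neither). Weights are averaged
over 10 independent runs; the top 14 of the 204 features are selected,
ties broken toward the lower column index.

By default selection runs on the full t = 0 dataset before any split —
that is the stated order of the original procedure, and it leaks test
instances into selection. `ExperimentConfig(select_on_train_only=True)`
instead reselects inside each repeat on that repeat's training indices,
which is the clean variant; the label-shuffle null in the test suite
exercises the permutation-null machinery (`shuffle_labels_seed`, which
shuffles labels *after* horizon relabeling — shuffling earlier would be
undone because relabeling re-stamps the pre-ictal window from the
seizure annotations).

## Classifier

One soft-margin RBF SVM per unordered class pair (6 binary models for 4
states), with per-class penalty C × w(class), where w(inter-ictal) = 1
and w(c) = count(inter-ictal)/count(c) — e.g. 1 / 9.4 / 15.67 / 9.4 for
the canonical 564/60/36/60 split. The quadratic programs are solved by
`sklearn.svm.SVC` (tol 1e-3, shrinking on); the one-vs-one construction,
class weighting, majority voting and the tie-break toward the most
frequent training class are implemented here rather than inherited from
a library's multi-class mode. Features are reduced to the selected 14
and z-scored with parameters fitted on the training split only.

(C, γ) are chosen by stratified 10-fold cross-validated accuracy over
C ∈ {2⁸, 2¹², 2¹⁶} × γ ∈ {2⁰, 2², …, 2¹⁰} (18 combinations), ties broken
toward smaller C then smaller γ. Stratification by the 4-state label is
assumed (unstated in the source; without it the pre-ictal class starves
folds). Tuning runs per (horizon, repeat) on that repeat's training
split.

## Evaluation

Metrics are pre-ictal-centred percentages from the 4×4 confusion table.
Two conventions are provided because the printed formulas and the prose
that claims equivalence with TP/FN definitions differ:

- `paper_eq78` (default for model reports): prediction-conditioned —
  Sensitivity = 100·N(pre→pre)/P(pre) over *predicted* pre-ictal,
  Specificity over predicted non-pre-ictal.
- `truth_conditioned`: the textbook TP/(TP+FN) and TN/(TN+FP).

S1 is the harmonic mean of the two. Zero-denominator cases return 0 with
a flag. Closed-form baselines: always/never-pre-ictal, the
frequency-matched ("informed") random predictor and random_p(p). At the
canonical frequencies the informed predictor scores Accuracy 63.0
(Σ p_c² over the 4-class matched predictor), Sensitivity 8.33,
Specificity 91.67, S1 15.27… (truncates to 15.2); random_p(0.5) is
50/50/50 truth-conditioned. The "always pre-ictal" accuracy computed
from the frequencies is 8.33%, not the 5% sometimes quoted alongside
them; this package computes from the frequencies. The canonical
frequencies as printed sum to 0.99996, so the ClassFrequencies sum check
tolerates rounding at the fourth decimal. Per-horizon S1 summaries
average per-trial S1 (not the harmonic mean of averaged
sensitivity/specificity); the summary table's mode is computed on values
rounded to 2 decimals.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not physiological EEG. Background: a shared latent AR(2) source plus
independent per-channel AR(2) noise (coefficients 1.3, −0.4 — stable,
low-pass) and a 10 Hz alpha oscillation with random phase. Ictal: 4×
amplitude surge plus a 3 Hz rhythmic component. Post-ictal: amplitude
suppression (gain 0.5) recovering linearly over 300 s, so the state is
learnable. Pre-ictal: the alpha component is multiplied by
(1 + effect·ramp) and a mean shift effect·ramp·σ is added, with the ramp
rising linearly from 0 at onset − 300 s to 1 at onset; `preictal_effect`
= 0 makes pre-ictal windows statistically indistinguishable from
inter-ictal, the default 1.0 gives a moderate, detectable shift.
Optional artefacts are high-amplitude square transients. Per-file
sub-seeds are spawned deterministically from a master seed; identical
configs and seeds give bit-identical records.

What passing tests on this generator do *not* show: performance on real
EEG. The generator's classes are far cleaner than clinical data, channel
structure is a single shared source, and instances from overlapping LTE
windows are strongly temporally correlated — with the seizure at a fixed
offset in every file, time-correlated features (accumulated energy
especially) let the random 70/30 split separate classes even with no
spectral pre-ictal shift. The label-shuffle null and the
effect-monotonicity checks are therefore the meaningful desk-scale
validations, not the absolute S1 values.

## Problem sizes used in tests and the acceptance script

Pipeline-level tests use three 1200-s single-seizure files per synthetic
patient (full 5-minute neighbourhoods preserved), a reduced grid
(C ∈ {2⁸, 2¹²}, γ ∈ {2⁰, 2⁴}), horizons {0} or {0, 1, 5} and 2–3
repeats. The acceptance script uses full one-hour files for the
bookkeeping quantities (720 × 204 extraction, five-file horizon-20
removal totals) and the closed-form baselines at the printed class
frequencies. Monte-Carlo metric checks use 10⁶ draws so the estimator
noise sits well inside the ±0.5-point agreement band.

## Known limitations

- No EDF/BDF readers; ASCII columns plus a plain-text sidecar only.
- Artefact handling follows expert annotations; no automatic detection.
- Single-channel (univariate) features only.
- The Lyapunov and correlation-dimension estimates at 1280-sample
  windows are feature-grade, not research-grade invariant estimates:
  they are stable inputs for classification, not converged dynamical
  quantities.
- The blocked-split caveat: the random split follows the source
  procedure despite temporal correlation between instances;
  `select_on_train_only` and the permutation null are provided as
  diagnostics, a full blocked-split protocol is not.
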