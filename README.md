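# asppr

Advance seizure prediction via pre-ictal relabeling, for intracranial
EEG. The package is aimed at neuroinformatics researchers who want a
complete, testable, patient-specific prediction pipeline: multi-channel
EEG in, horizon-specific seizure-onset predictions and
baseline-referenced evaluation out.

## The method

A patient's one-hour "ictal files" (6 channels, 256 Hz, one seizure
each) are converted into one instance per 5-second tick — 720 instances
per hour, each with 204 features (34 per channel): windowed signal
energy (5 s / 9 s / 180 s), accumulated energy, db4 level-4 wavelet
sub-band energies, the maximal Lyapunov exponent and correlation
dimension, statistical moments, spectral band powers (δ/θ/α/β/γ) and
spectral edge frequencies (SEF-50/90).

Instances are labeled *ictal*, *pre-ictal* (the 5 minutes before
onset), *post-ictal* (5 minutes after offset) or *inter-ictal*. The
horizon-N dataset retargets the pre-ictal class at onset N to N+5
minutes ahead by removing the N minutes before onset and relabeling the
5 minutes before that, for N = 0 … 20.

Per patient: ReliefF (10 runs, mean weights) selects the top 14 of the
204 features; for each horizon and each of 10 stratified 70/30 splits a
one-vs-one soft-margin RBF SVM is trained with per-class penalties
C·w(c), w(c) = n(inter)/n(c), and (C, γ) grid-searched over
{2⁸, 2¹², 2¹⁶} × {2⁰, 2², …, 2¹⁰} by 10-fold CV accuracy. Test
predictions are scored with pre-ictal-centred Sensitivity
(100·N(pre→pre)/P(pre)), Specificity (the non-pre analogue) and their
harmonic mean, the S1-score, against closed-form baseline and random
predictors.

Real clinical recordings are not bundled; a deterministic synthetic
generator (`asppr.synth`) produces annotated records with the same
statistical structure — AR(2)-plus-alpha background, an ictal amplitude
surge, post-ictal suppression and a *controllable* graded pre-ictal
spectral/amplitude shift — so every stage is testable end to end.

## Worked example

Closed-form baselines at the canonical class frequencies
(`python examples/04_baseline_metrics.py`):

```
         predictor     acc    sens    spec      s1
  always pre-ictal    8.33  100.00    0.00    0.00
   never pre-ictal   78.33    0.00  100.00    0.00
   informed random   62.99    8.33   91.67   15.28
      random p=0.5   50.00   50.00   50.00   50.00
```

The informed random predictor — it emits "pre-ictal" at exactly the
true pre-ictal rate — is the strongest trivial baseline at S1 = 15.28
(15.2 truncated); any useful model must clear it decisively.

Horizon relabeling bookkeeping (`python examples/03_horizon_relabeling.py`):

```
t=0 dataset: 720 instances, 60 pre-ictal
  N  removed  relabeled  instances   pre
  0        0          0        720    60
  1       12         12        708    60
  5       60         60        660    60
 20      240         60        480    60
```

The pre-ictal class keeps its 60 instances at every horizon — the
5-minute window just moves earlier — while the dataset shrinks by 12
instances per horizon minute.

The remaining scripts in `examples/` generate a synthetic patient,
extract the 204-feature stream, and run the full experiment
(`05_full_experiment.py`, a few minutes). A thin CLI mirrors the same
steps: `asppr synth`, `asppr extract`, `asppr relabel`,
`asppr baselines`, `asppr run`.

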