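"""Closed-form baseline and random-predictor reference metrics.

Any reported Sensitivity/Specificity/S1 should be read against what
trivial predictors achieve at the canonical class frequencies
(inter-ictal 0.7833, pre-ictal 0.08333, ictal 0.05, post-ictal 0.08333).
"""

from asppr import ClassFrequencies, baseline_expected_metrics

freqs = ClassFrequencies.canonical()
rows = [("always pre-ictal", "always_pre", None, "truth_conditioned"),
        ("never pre-ictal", "never_pre", None, "truth_conditioned"),
        ("informed random", "informed_random", None, "paper_eq78"),
        ("random p=0.5", "random_p", 0.5, "truth_conditioned")]

print(f"{'predictor':>18} {'acc':>7} {'sens':>7} {'spec':>7} {'s1':>7}")
for name, kind, p, convention in rows:
    m = baseline_expected_metrics(freqs, kind, p=p, convention=convention)
    print(f"{name:>18} {m['accuracy']:7.2f} {m['sensitivity']:7.2f} "
          f"{m['specificity']:7.2f} {m['s1']:7.2f}")
# The informed random predictor (emits pre-ictal at the true class rate)
# is the strongest trivial baseline: S1 = 15.28 (truncates to 15.2).
# A useful predictor must clear that bar by a wide margin.
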