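"""Accuracy, Sensitivity, Specificity and S1-score, plus analytic baselines.

Two conventions are implemented for Sensitivity/Specificity:

``paper_eq78`` (default for model reports)
    Prediction-conditioned, as printed: Sensitivity is the percentage of
    *pre-ictal predictions* that were truly pre-ictal,
    ``100 * N(pre->pre) / P(pre)``; Specificity is the percentage of
    non-pre-ictal predictions that came from non-pre-ictal instances.

``truth_conditioned``
    The textbook definitions: Sensitivity = 100*TP/(TP+FN) over true
    pre-ictal instances, Specificity = 100*TN/(TN+FP) over true
    non-pre-ictal instances.

The S1-score is the harmonic mean of Sensitivity and Specificity.  The
closed-form baselines cover the always/never-pre-ictal predictors, the
frequency-matched ("well-informed") random predictor and the generic
``random_p(p)`` predictor; with the canonical class frequencies
(0.08333 / 0.05 / 0.7833 / 0.08333) the informed random predictor scores
Accuracy 63.0, Sensitivity 8.33, Specificity 91.67 and S1 15.2 (truncated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import LABELS
from .exceptions import ValidationError

#: canonical one-hour ictal-file class frequencies (inter, pre, ictal, post)
CANONICAL_FREQUENCIES = {"inter-ictal": 0.7833, "pre-ictal": 0.08333,
                         "ictal": 0.05, "post-ictal": 0.08333}


@dataclass
class ConfusionTable:
    """4x4 table of counts N(true -> predicted), class order as LABELS."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ValidationError("confusion table must be 4x4 non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassFrequencies:
    """Class probabilities for the analytic baseline predictors."""

    p_inter: float
    p_pre: float
    p_ictal: float
    p_post: float

    def __post_init__(self):
        # the canonical printed frequencies are rounded and sum to 0.99996,
        # so the sum check allows rounding at the 4th decimal
        vec = np.array([self.p_inter, self.p_pre, self.p_ictal, self.p_post])
        if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-4:
            raise ValidationError(
                f"class frequencies must be non-negative and sum to 1, "
                f"got {vec.tolist()}")

    @classmethod
    def canonical(cls) -> "ClassFrequencies":
        return cls(p_inter=CANONICAL_FREQUENCIES["inter-ictal"],
                   p_pre=CANONICAL_FREQUENCIES["pre-ictal"],
                   p_ictal=CANONICAL_FREQUENCIES["ictal"],
                   p_post=CANONICAL_FREQUENCIES["post-ictal"])

    def as_dict(self) -> dict:
        return {"inter-ictal": self.p_inter, "pre-ictal": self.p_pre,
                "ictal": self.p_ictal, "post-ictal": self.p_post}


def confusion(y_true, y_pred) -> ConfusionTable:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred must have equal length")
    unknown = (set(y_true) | set(y_pred)) - set(LABELS)
    if unknown:
        raise ValidationError(f"unknown labels: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(LABELS)}
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionTable(counts=counts)


def _harmonic(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def metrics(table: ConfusionTable, convention: str = "paper_eq78",
            return_flags: bool = False):
    """(accuracy, sensitivity, specificity, s1) in percent.

    Prediction-conditioned quantities with a zero denominator are
    returned as 0 (flagged when ``return_flags`` is set).
    """
    if convention not in ("paper_eq78", "truth_conditioned"):
        raise ValidationError(f"unknown convention {convention!r}")
    c = table.counts
    total = table.total
    if total == 0:
        raise ValidationError("empty confusion table")
    pre = LABELS.index("pre-ictal")
    accuracy = 100.0 * np.trace(c) / total
    flags = {"sensitivity": False, "specificity": False}

    if convention == "paper_eq78":
        pred_pre = c[:, pre].sum()
        pred_non = total - pred_pre
        if pred_pre == 0:
            sensitivity, flags["sensitivity"] = 0.0, True
        else:
            sensitivity = 100.0 * c[pre, pre] / pred_pre
        non = [i for i in range(4) if i != pre]
        if pred_non == 0:
            specificity, flags["specificity"] = 0.0, True
        else:
            specificity = 100.0 * c[np.ix_(non, non)].sum() / pred_non
    else:
        true_pre = c[pre, :].sum()
        true_non = total - true_pre
        if true_pre == 0:
            sensitivity, flags["sensitivity"] = 0.0, True
        else:
            sensitivity = 100.0 * c[pre, pre] / true_pre
        if true_non == 0:
            specificity, flags["specificity"] = 0.0, True
        else:
            non = [i for i in range(4) if i != pre]
            specificity = 100.0 * (c[non, :].sum() - c[non, pre].sum()) / true_non

    s1 = _harmonic(sensitivity, specificity)
    out = (accuracy, sensitivity, specificity, s1)
    return (out, flags) if return_flags else out


def baseline_expected_metrics(freqs: ClassFrequencies, predictor: str,
                              p: float = None,
                              convention: str = "paper_eq78") -> dict:
    """Closed-form expected metrics for a baseline/random predictor.

    ``predictor`` is one of ``always_pre``, ``never_pre``,
    ``informed_random`` (emits pre-ictal with probability equal to the
    pre-ictal frequency; its Accuracy is that of the 4-class
    frequency-matched predictor, sum of squared frequencies) or
    ``random_p`` (emits pre-ictal with probability ``p``).
    """
    if predictor not in ("always_pre", "never_pre", "informed_random",
                         "random_p"):
        raise ValidationError(f"unknown predictor {predictor!r}")
    if convention not in ("paper_eq78", "truth_conditioned"):
        raise ValidationError(f"unknown convention {convention!r}")
    fp = freqs.as_dict()
    q = fp["pre-ictal"]
    if predictor == "random_p":
        if p is None or not (0.0 <= p <= 1.0):
            raise ValidationError("random_p requires p in [0, 1]")
        emit = p
    elif predictor == "always_pre":
        emit = 1.0
    elif predictor == "never_pre":
        emit = 0.0
    else:
        emit = q

    # predictions are independent of the truth for every baseline, so both
    # conventions have simple closed forms
    if convention == "truth_conditioned":
        sensitivity = 100.0 * emit
        specificity = 100.0 * (1.0 - emit)
    else:
        # P(true pre | predicted pre) = q; P(true non-pre | predicted non-pre)
        sensitivity = 100.0 * q if emit > 0 else 0.0
        specificity = 100.0 * (1.0 - q) if emit < 1 else 0.0

    if predictor == "informed_random":
        # 4-class frequency-matched predictor
        accuracy = 100.0 * sum(v ** 2 for v in fp.values())
    elif predictor == "always_pre":
        accuracy = 100.0 * q
    elif predictor == "never_pre":
        # best non-pre constant prediction: the majority class
        accuracy = 100.0 * max(v for c, v in fp.items() if c != "pre-ictal")
    else:
        accuracy = 100.0 * (emit * q + (1 - emit) * (1 - q))

    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity,
            "s1": _harmonic(sensitivity, specificity)}


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate toward zero to the given number of decimals (15.27 -> 15.2)."""
    factor = 10.0 ** decimals
    return np.trunc(value * factor) / factor
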