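"""Four-state instance labeling and horizon relabeling.

Instances live on a 5-second clock starting at t = 5 s; the window of an
instance ends at its timestamp.  The instance at time ``t`` is *ictal*
if ``t`` lies in ``(onset, offset]``, *pre-ictal* in ``(onset-300, onset]``,
*post-ictal* in ``(offset, offset+300]`` and *inter-ictal* otherwise.
With the canonical one-hour file and a 180-s seizure this yields
60 / 36 / 60 / 564 instances (frequencies 0.08333 / 0.05 / 0.08333 / 0.7833).

A horizon-``N`` dataset retargets the pre-ictal class at seizure onset
``N`` to ``N+5`` minutes ahead: instances in ``(onset - 60N, onset]`` are
removed and instances in ``(onset - 60(N+5), onset - 60N]`` become
pre-ictal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .eeg_io import FeatureMatrix
from .exceptions import ValidationError

INSTANCE_STEP_S = 5.0
NEIGHBORHOOD_S = 300.0  # pre- and post-ictal window length

# precedence when windows of multiple seizures overlap (highest wins)
_PRECEDENCE = {"ictal": 3, "pre-ictal": 2, "post-ictal": 1, "inter-ictal": 0}


def instance_times(duration_s: float, step_s: float = INSTANCE_STEP_S) -> np.ndarray:
    """Instance timestamps ``step, 2*step, ...`` up to the record duration."""
    n = int(np.floor(duration_s / step_s + 1e-9))
    return step_s * np.arange(1, n + 1)


def label_instances(timestamps, seizures) -> np.ndarray:
    """Assign 4-state labels to instance timestamps.

    Boundary convention: windows are anchored on onset/offset with the
    instance whose window ends exactly at onset counted as the last
    pre-ictal instance (half-open on the early side).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    labels = np.full(len(timestamps), "inter-ictal", dtype=object)
    rank = np.zeros(len(timestamps), dtype=int)
    for onset, offset in seizures:
        if onset < NEIGHBORHOOD_S:
            warnings.warn(
                f"seizure at {onset} s starts within 300 s of file start; "
                "pre-ictal window truncated", stacklevel=2)
        for lab, lo, hi in (
            ("ictal", onset, offset),
            ("pre-ictal", onset - NEIGHBORHOOD_S, onset),
            ("post-ictal", offset, offset + NEIGHBORHOOD_S),
        ):
            mask = (timestamps > lo + 1e-9) & (timestamps <= hi + 1e-9)
            take = mask & (_PRECEDENCE[lab] > rank)
            labels[take] = lab
            rank[take] = _PRECEDENCE[lab]
    return labels


@dataclass
class HorizonDataset:
    """A horizon-relabeled feature dataset with its bookkeeping counts."""

    matrix: FeatureMatrix
    horizon_min: int
    removed_count: int
    relabeled_count: int


def relabel_for_horizon(dataset: FeatureMatrix, horizon_min: int,
                        seizures) -> HorizonDataset:
    """Build the horizon-``N`` dataset from a t=0 labeled dataset.

    Per seizure, instances in ``(onset - 60N, onset]`` are dropped and
    formerly later instances in ``(onset - 60(N+5), onset - 60N]`` are
    labeled pre-ictal.  ``relabeled_count`` counts actual label changes
    (inter-ictal → pre-ictal); instances that were already pre-ictal at
    t=0 do not add to it.
    """
    if horizon_min != int(horizon_min) or horizon_min < 0:
        raise ValidationError(f"horizon must be a non-negative integer number "
                              f"of minutes, got {horizon_min}")
    n = int(horizon_min)
    t = dataset.timestamps
    labels = dataset.labels.copy()
    keep = np.ones(len(t), dtype=bool)
    relabeled = 0
    for onset, _offset in seizures:
        rm = (t > onset - 60.0 * n + 1e-9) & (t <= onset + 1e-9) & keep
        # never drop ictal/post-ictal instances; the removal window ends at onset
        rm &= np.isin(labels, ("pre-ictal", "inter-ictal"))
        keep &= ~rm
        lo, hi = onset - 60.0 * (n + 5), onset - 60.0 * n
        re = (t > lo + 1e-9) & (t <= hi + 1e-9) & keep
        relabeled += int(np.sum(re & (labels != "pre-ictal")))
        labels[re] = "pre-ictal"
    removed = int(np.sum(~keep))
    out = FeatureMatrix(values=dataset.values[keep], timestamps=t[keep],
                        labels=labels[keep],
                        column_names=list(dataset.column_names))
    return HorizonDataset(matrix=out, horizon_min=n,
                          removed_count=removed, relabeled_count=relabeled)
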