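"""Artefact removal prior to feature extraction.

Two policies: ``interpolate`` (default) replaces artefact samples with a
linear bridge between the interval endpoints, keeping the 5-s instance
clock aligned to wall time; ``excise`` deletes the samples and shifts all
later annotation times earlier by the removed duration.  Artefact
intervals overlapping a seizure are an error — ictal ground truth must
never be altered.
"""

from __future__ import annotations

import numpy as np

from .eeg_io import AnnotationSet, EEGRecord
from .exceptions import ValidationError


def merge_intervals(intervals):
    """Union of possibly-overlapping half-open intervals, sorted."""
    merged = []
    for a, b in sorted((float(a), float(b)) for a, b in intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def remove_artefacts(record: EEGRecord, annotations: AnnotationSet,
                     policy: str = "interpolate"):
    """Remove annotated artefact intervals from a record.

    Returns ``(record, annotations)``; under ``excise`` the seizure times
    in the returned annotations are shifted by the removed duration ahead
    of them, under ``interpolate`` they are unchanged.
    """
    if policy not in ("excise", "interpolate"):
        raise ValidationError(f"unknown artefact policy {policy!r}")
    annotations.validate_within(record.duration_s)
    artefacts = merge_intervals(annotations.artefacts)
    if not artefacts:
        return record, AnnotationSet(seizures=list(annotations.seizures))
    for a, b in artefacts:
        for on, off in annotations.seizures:
            if a < off and on < b:
                raise ValidationError(
                    f"artefact ({a}, {b}) overlaps seizure ({on}, {off}); "
                    "seizure data must not be removed")

    fs = record.fs
    bounds = [(int(round(a * fs)), int(round(b * fs))) for a, b in artefacts]

    if policy == "interpolate":
        samples = record.samples.copy()
        n = samples.shape[1]
        for i0, i1 in bounds:
            i1 = min(i1, n)
            left = samples[:, i0 - 1] if i0 > 0 else samples[:, min(i1, n - 1)]
            right = samples[:, i1] if i1 < n else samples[:, i0 - 1]
            w = np.linspace(0.0, 1.0, i1 - i0 + 2)[1:-1]
            samples[:, i0:i1] = left[:, None] * (1 - w) + right[:, None] * w
        out = EEGRecord(samples=samples, fs=fs,
                        channel_names=list(record.channel_names), t0=record.t0)
        return out, AnnotationSet(seizures=list(annotations.seizures))

    # excise: drop samples, shift later annotation times earlier
    keep = np.ones(record.n_samples, dtype=bool)
    for i0, i1 in bounds:
        keep[i0:i1] = False
    out = EEGRecord(samples=record.samples[:, keep], fs=fs,
                    channel_names=list(record.channel_names), t0=record.t0)

    def shift(t):
        removed = sum(min(b, t) - a for a, b in artefacts if a < t)
        return t - removed

    seizures = [(shift(on), shift(off)) for on, off in annotations.seizures]
    return out, AnnotationSet(seizures=seizures)
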