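"""Multi-class ReliefF feature weighting and top-k selection.

ReliefF scores each feature by how well it separates near neighbours of
different classes.  For each of ``m`` sampled instances R the k nearest
hits (same class) and k nearest misses per other class are found; the
weight update penalises feature differences to hits and rewards
differences to misses, with each miss class weighted by its prior
probability renormalised over the classes other than R's
(Robnik-Sikonja & Kononenko).  Features are min-max scaled so the diff
function lies in [0, 1]; distances are Manhattan on the scaled features.

The ranking used downstream is the mean weight over 10 independent runs;
the 14 highest-ranked of the 204 features are selected (ties broken by
lower column index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError


@dataclass
class FeatureRanking:
    """Per-run and mean ReliefF weights with the implied rank order."""

    weights_per_run: np.ndarray  # (runs, features)
    mean_weights: np.ndarray
    rank_order: np.ndarray       # feature indices, descending mean weight

    @property
    def n_runs(self) -> int:
        return self.weights_per_run.shape[0]


def _minmax_scale(X):
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def relieff_weights(X, y, k: int = 10, m: int = None, seed: int = 0,
                    warn=None) -> np.ndarray:
    """One ReliefF run: per-feature weights from ``m`` sampled instances.

    ``m`` defaults to min(n, 1000).  If a class has fewer than ``k + 1``
    members, k is reduced for that class (a warning is emitted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("ReliefF needs at least two classes")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if m is None:
        m = min(n, 1000)
    if m < 1:
        raise ValidationError("m must be >= 1")

    priors = dict(zip(classes, counts / n))
    Xs = _minmax_scale(X)
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in by_class.items():
        if len(idx) < k + 1:
            import warnings
            warnings.warn(f"class {c!r} has only {len(idx)} instances; "
                          f"reducing its neighbour count below k={k}",
                          stacklevel=2)

    rng = np.random.default_rng(seed)
    sample = rng.choice(n, size=m, replace=m > n) if m != n else np.arange(n)
    w = np.zeros(f)
    for r in sample:
        xr = Xs[r]
        cr = y[r]
        dists = np.abs(Xs - xr).sum(axis=1)
        # hits: nearest same-class neighbours, excluding R itself
        hit_idx = by_class[cr][by_class[cr] != r]
        kh = min(k, len(hit_idx))
        if kh > 0:
            hits = hit_idx[np.argsort(dists[hit_idx], kind="stable")[:kh]]
            w -= np.abs(Xs[hits] - xr).sum(axis=0) / (m * kh)
        denom = 1.0 - priors[cr]
        for c in classes:
            if c == cr:
                continue
            miss_idx = by_class[c]
            km = min(k, len(miss_idx))
            if km == 0:
                continue
            misses = miss_idx[np.argsort(dists[miss_idx], kind="stable")[:km]]
            w += (priors[c] / denom) * np.abs(Xs[misses] - xr).sum(axis=0) / (m * km)
    return w


def run_relieff(X, y, n_runs: int = 10, k: int = 10, m: int = None,
                seed: int = 0) -> np.ndarray:
    """Stack ``n_runs`` independent ReliefF weight vectors (runs x features)."""
    ss = np.random.SeedSequence(seed)
    runs = [relieff_weights(X, y, k=k, m=m,
                            seed=int(child.generate_state(1)[0] % (2 ** 31)))
            for child in ss.spawn(n_runs)]
    return np.vstack(runs)


def rank_and_select(weight_runs, n_select: int = 14):
    """Mean weights over runs, descending rank order and the top-n indices.

    Ties in mean weight are broken in favour of the lower column index.
    """
    weight_runs = np.atleast_2d(np.asarray(weight_runs, dtype=float))
    n_features = weight_runs.shape[1]
    if n_select > n_features:
        raise ValidationError(
            f"cannot select {n_select} of {n_features} features")
    mean_weights = weight_runs.mean(axis=0)
    # stable sort on -weights keeps lower indices first among ties
    order = np.argsort(-mean_weights, kind="stable")
    ranking = FeatureRanking(weights_per_run=weight_runs,
                             mean_weights=mean_weights, rank_order=order)
    return ranking, order[:n_select]
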