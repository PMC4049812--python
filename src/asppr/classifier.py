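"""Class-weighted one-against-one soft-margin RBF SVM.

One binary soft-margin SVM is trained per unordered class pair (6 models
for the 4 brain states), each with per-class error penalty C x weight(class)
where weight(inter-ictal) = 1 and weight(c) = count(inter-ictal)/count(c)
for the minority classes.  Prediction is by majority vote over the binary
models; ties are broken in favour of the class most frequent in the
training set.  Hyperparameters (C, gamma) are chosen by stratified
10-fold cross-validated accuracy over the grid
C in {2^8, 2^12, 2^16}, gamma in {2^0, 2^2, ..., 2^10}, with ties broken
by smaller C then smaller gamma.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .eeg_io import LABELS
from .exceptions import PredictionError, TrainingError, ValidationError

DEFAULT_C_GRID = tuple(2.0 ** e for e in (8, 12, 16))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in (0, 2, 4, 6, 8, 10))


def compute_class_weights(labels) -> dict:
    """Per-class penalty multipliers: 1 for inter-ictal, count ratios otherwise."""
    labels = np.asarray(labels)
    counts = {c: int(np.sum(labels == c)) for c in LABELS}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise TrainingError(f"missing class(es) in training data: {missing}")
    ref = counts["inter-ictal"]
    return {c: (1.0 if c == "inter-ictal" else ref / counts[c]) for c in LABELS}


@dataclass
class TrainedModel:
    """One-vs-one RBF SVM bundle with scaling and tie-break bookkeeping."""

    binary_models: dict            # (class_a, class_b) -> fitted SVC
    selected_features: np.ndarray  # column indices the model expects
    C: float
    gamma: float
    class_weights: dict
    class_frequencies: dict        # training-set label frequencies
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    classes: tuple = field(default=LABELS)

    def scale(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_std


def fit_scaler(X):
    """Z-score parameters fitted on the training split only."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def train(X, y, C: float, gamma: float, class_weights: dict = None,
          selected_features=None, tol: float = 1e-3) -> TrainedModel:
    """Train the one-vs-one bundle on (already selected, unscaled) features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise TrainingError("non-finite feature values in training data")
    present = [c for c in LABELS if (y == c).any()]
    if len(present) < 2:
        raise TrainingError("need at least two classes to train")
    if class_weights is None:
        class_weights = ({c: 1.0 for c in present} if len(present) < 4
                         else compute_class_weights(y))
    mean, std = fit_scaler(X)
    Xs = (X - mean) / std
    models = {}
    for a, b in itertools.combinations(present, 2):
        mask = (y == a) | (y == b)
        clf = SVC(kernel="rbf", C=C, gamma=gamma, tol=tol,
                  class_weight={a: class_weights[a], b: class_weights[b]})
        clf.fit(Xs[mask], y[mask])
        models[(a, b)] = clf
    freqs = {c: float(np.mean(y == c)) for c in present}
    sel = (np.arange(X.shape[1]) if selected_features is None
           else np.asarray(selected_features))
    return TrainedModel(binary_models=models, selected_features=sel,
                        C=C, gamma=gamma, class_weights=dict(class_weights),
                        class_frequencies=freqs, scaler_mean=mean,
                        scaler_std=std, classes=tuple(present))


def predict(model: TrainedModel, X) -> np.ndarray:
    """Majority vote over the binary models; ties go to the most frequent class."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.scaler_mean):
        raise PredictionError(
            f"expected {len(model.scaler_mean)} features, got {X.shape[1]}")
    Xs = model.scale(X)
    n = X.shape[0]
    votes = {c: np.zeros(n, dtype=int) for c in model.classes}
    for (a, b), clf in model.binary_models.items():
        pred = clf.predict(Xs)
        votes[a] += pred == a
        votes[b] += pred == b
    vote_matrix = np.column_stack([votes[c] for c in model.classes])
    out = np.empty(n, dtype=object)
    freqs = np.array([model.class_frequencies[c] for c in model.classes])
    for i in range(n):
        row = vote_matrix[i]
        top = np.flatnonzero(row == row.max())
        if len(top) == 1:
            out[i] = model.classes[top[0]]
        else:
            out[i] = model.classes[top[np.argmax(freqs[top])]]
    return out


def cv_accuracy(X, y, C: float, gamma: float, folds: int = 10,
                seed: int = 0) -> float:
    """Stratified k-fold cross-validated 4-state accuracy for one (C, gamma)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < folds:
        warnings.warn(f"smallest class has {counts.min()} members; "
                      f"reducing CV folds from {folds} to {eff_folds}",
                      stacklevel=2)
    if eff_folds < 2:
        raise ValidationError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        model = train(X[tr], y[tr], C, gamma)
        correct += int(np.sum(predict(model, X[te]) == y[te]))
    return correct / len(y)


def grid_search(X, y, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                folds: int = 10, seed: int = 0):
    """Pick (C, gamma) by CV accuracy; ties favour smaller C, then smaller gamma."""
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ValidationError("empty hyperparameter grid")
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            acc = cv_accuracy(X, y, C, gamma, folds=folds, seed=seed)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    return best[1], best[2]
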