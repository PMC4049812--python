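"""Per-patient experiment orchestration.

For one patient: concatenate the feature matrices of the patient's ictal
files, pick the top-14 features by ReliefF on the t=0 dataset, then for
every horizon N in 0..20 and every repeat run a stratified 70/30 split,
grid-search (C, gamma) by 10-fold CV on the training split, train the
class-weighted one-vs-one RBF SVM and evaluate the held-out 30% with the
pre-ictal-centred metrics.  Ten repeats per horizon by default, each with
its own derived sub-seed; identical config and seed reproduce the result
table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classifier, evaluation, relieff
from .eeg_io import AnnotationSet, EEGRecord, FeatureMatrix
from .exceptions import ValidationError
from .features import FeatureConfig, extract_feature_matrix
from .labeling import relabel_for_horizon

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "s1")


@dataclass
class ExperimentConfig:
    """Study-design parameters for one patient experiment."""

    horizons: tuple = tuple(range(21))
    repeats: int = 10
    train_fraction: float = 0.70
    seed: int = 0
    n_select: int = 14
    relieff_runs: int = 10
    relieff_k: int = 10
    relieff_m: int = None
    c_grid: tuple = classifier.DEFAULT_C_GRID
    gamma_grid: tuple = classifier.DEFAULT_GAMMA_GRID
    cv_folds: int = 10
    metric_convention: str = "paper_eq78"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    select_on_train_only: bool = False
    #: diagnostic permutation null: shuffle labels after horizon relabeling
    shuffle_labels_seed: int = None

    def validate(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass
class ResultTable:
    """Per-(horizon, repeat) metrics plus the selected feature indices."""

    rows: pd.DataFrame
    selected_features: np.ndarray
    config: ExperimentConfig

    def per_horizon(self) -> pd.DataFrame:
        return self.rows.groupby("horizon")[list(METRIC_NAMES)].mean()


def _as_matrix(item, config: ExperimentConfig, seed: int) -> FeatureMatrix:
    if isinstance(item, FeatureMatrix):
        return item
    record, annotations = item
    return extract_feature_matrix(record, annotations,
                                  config=config.feature_config, seed=seed)


def concatenate_matrices(matrices) -> tuple:
    """Stack per-file matrices; returns (values, labels, seizure-relative info).

    Timestamps are kept per file for relabeling, so this returns the list
    itself; use together with per-file seizure annotations.
    """
    return matrices


def run_patient(files, config: ExperimentConfig = None,
                annotations_per_file=None) -> ResultTable:
    """Run the full advance-prediction experiment for one patient.

    ``files`` is a list of (EEGRecord, AnnotationSet) pairs, or a list of
    pre-extracted FeatureMatrix objects (then ``annotations_per_file``
    must give the matching AnnotationSet per matrix).
    """
    config = config or ExperimentConfig()
    config.validate()
    rng_root = np.random.SeedSequence(config.seed)
    extract_seeds, relieff_seed, split_root = rng_root.spawn(3)

    matrices, annots = [], []
    for i, item in enumerate(files):
        sub = int(extract_seeds.generate_state(len(files))[i] % (2 ** 31))
        matrices.append(_as_matrix(item, config, sub))
        if isinstance(item, FeatureMatrix):
            if annotations_per_file is None:
                raise ValidationError(
                    "annotations_per_file is required when passing "
                    "pre-extracted matrices")
            annots.append(annotations_per_file[i])
        else:
            annots.append(item[1])
    if not any(a.seizures for a in annots):
        raise ValidationError("patient has no seizure in any file")

    # feature selection on the concatenated t=0 dataset (the paper's order:
    # selection precedes the train/test split, which leaks test labels into
    # selection; select_on_train_only=True defers selection to each repeat's
    # training split instead)
    X0 = np.vstack([m.values for m in matrices])
    y0 = np.concatenate([m.labels for m in matrices])
    rl_seed = int(relieff_seed.generate_state(1)[0] % (2 ** 31))
    selected = None
    if not config.select_on_train_only:
        weight_runs = relieff.run_relieff(
            X0, y0, n_runs=config.relieff_runs, k=config.relieff_k,
            m=config.relieff_m, seed=rl_seed)
        _, selected = relieff.rank_and_select(weight_runs, config.n_select)

    records = []
    split_seeds = split_root.generate_state(len(config.horizons) *
                                            config.repeats) % (2 ** 31)
    si = 0
    for horizon in config.horizons:
        # relabel each file against its own seizure clock, then concatenate
        parts = [relabel_for_horizon(m, horizon, a.seizures).matrix
                 for m, a in zip(matrices, annots)]
        X_full = np.vstack([p.values for p in parts])
        y = np.concatenate([p.labels for p in parts])
        if config.shuffle_labels_seed is not None:
            np.random.default_rng(config.shuffle_labels_seed +
                                  horizon).shuffle(y)
        for repeat in range(config.repeats):
            seed = int(split_seeds[si]); si += 1
            idx = np.arange(len(y))
            tr, te = train_test_split(idx, train_size=config.train_fraction,
                                      stratify=y, random_state=seed)
            if config.select_on_train_only:
                weight_runs = relieff.run_relieff(
                    X_full[tr], y[tr], n_runs=config.relieff_runs,
                    k=config.relieff_k, m=config.relieff_m,
                    seed=rl_seed + repeat)
                _, sel = relieff.rank_and_select(weight_runs, config.n_select)
            else:
                sel = selected
            X = X_full[:, sel]
            C, gamma = classifier.grid_search(
                X[tr], y[tr], c_grid=config.c_grid,
                gamma_grid=config.gamma_grid, folds=config.cv_folds,
                seed=seed)
            weights = classifier.compute_class_weights(y[tr])
            model = classifier.train(X[tr], y[tr], C, gamma, weights,
                                     selected_features=sel)
            y_pred = classifier.predict(model, X[te])
            table = evaluation.confusion(y[te], y_pred)
            acc, ss, sp, s1 = evaluation.metrics(
                table, convention=config.metric_convention)
            records.append({"horizon": horizon, "repeat": repeat,
                            "C": C, "gamma": gamma, "accuracy": acc,
                            "sensitivity": ss, "specificity": sp, "s1": s1})
    rows = pd.DataFrame.from_records(records)
    # with per-repeat selection the last repeat's choice is reported
    return ResultTable(rows=rows,
                       selected_features=selected if selected is not None
                       else sel, config=config)


def summarize(results: ResultTable) -> pd.DataFrame:
    """Summary statistics of the per-horizon mean metrics.

    min / max / mean / median / mode / std / range across horizons, plus
    the values at the first and last horizon.  The mode is computed on
    values rounded to 2 decimals.
    """
    per_h = results.per_horizon()
    if per_h.empty:
        raise ValidationError("empty result table")
    out = {}
    for metric in METRIC_NAMES:
        v = per_h[metric].to_numpy()
        rounded = np.round(v, 2)
        vals, counts = np.unique(rounded, return_counts=True)
        out[metric] = {
            "min": v.min(), "max": v.max(), "mean": v.mean(),
            "median": float(np.median(v)), "mode": float(vals[counts.argmax()]),
            "std": v.std(ddof=1) if len(v) > 1 else 0.0,
            "range": v.max() - v.min(),
            "at_first_horizon": v[0], "at_last_horizon": v[-1],
        }
    return pd.DataFrame(out)
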