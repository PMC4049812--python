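"""Shared fixtures.

The expensive fixtures (full-hour extraction, the effect-level study
matrices) are session-scoped so the cost is paid once per run; everything
else is generated fresh and small.
"""

import numpy as np
import pytest

from asppr import (AnnotationSet, SynthConfig, extract_feature_matrix,
                   generate_record)

# study conditions for the scaled-down pipeline fixtures: 1200-s single-
# seizure files with the full 5-minute pre/post neighbourhoods intact
PATIENT_FILE_KW = dict(duration_s=1200.0, seizure_onset_s=600.0,
                       seizure_offset_s=690.0)
EFFECT_LEVELS = (0.0, 0.8, 2.5)
PATIENT_SEEDS = (101, 102, 103)


@pytest.fixture(scope="session")
def hour_record():
    """Canonical one-hour ictal file (seizure 1800-1980 s, default config)."""
    cfg = SynthConfig(seed=20)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def hour_matrix(hour_record):
    """Full 204-feature matrix of the canonical one-hour file."""
    record, annotations = hour_record
    return extract_feature_matrix(record, annotations, seed=20), annotations


@pytest.fixture(scope="session")
def effect_matrices():
    """Feature matrices for 3 files x 3 pre-ictal effect levels {0, 0.8, 2.5}."""
    out = {}
    for level in EFFECT_LEVELS:
        items = []
        for seed in PATIENT_SEEDS:
            cfg = SynthConfig(preictal_effect=level, seed=seed,
                              **PATIENT_FILE_KW)
            record, ann = generate_record(cfg)
            items.append((extract_feature_matrix(record, ann, seed=seed), ann))
        out[level] = items
    return out


@pytest.fixture
def short_record():
    """A 60-s record for IO/preprocess tests (no full seizure neighbourhood)."""
    cfg = SynthConfig(duration_s=60.0, seizure_onset_s=20.0,
                      seizure_offset_s=30.0, seed=5)
    return generate_record(cfg)


@pytest.fixture
def tiny_matrix():
    """A small hand-buildable feature matrix."""
    from asppr import FeatureMatrix
    n = 12
    rng = np.random.default_rng(0)
    return FeatureMatrix(values=rng.normal(size=(n, 3)),
                         timestamps=5.0 * np.arange(1, n + 1),
                         labels=np.array(["inter-ictal"] * n, dtype=object),
                         column_names=["ch1__se", "ch1__ste", "ch1__lte"])
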