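"""Readers and writers for EEG records, annotations and feature datasets.

The on-disk EEG format is plain ASCII: one row per sample, one numeric
column per channel, whitespace- or comma-delimited (dot decimal).
Annotations travel in a plain-text sidecar listing ``seizure`` and
``artefact`` intervals in seconds from record start (half-open
``[start, end)``).  Feature datasets round-trip either through CSV
(portable) or an HDF5 container (bit-exact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: the four brain-state labels, in canonical order
LABELS = ("inter-ictal", "pre-ictal", "ictal", "post-ictal")

#: per-channel feature codes in canonical column order (34 codes)
FEATURE_CODES = (
    ["se", "ste", "lte", "ae"]
    + [f"dwt_{band}_{win}" for band in ("b0_12p5", "b12p5_25", "b25_50", "b50_100")
       for win in ("ste", "lte")]
    + ["lyap", "cdim"]
    + [f"{mom}_{win}" for mom in ("mean", "skew", "kurt") for win in ("ste", "lte")]
    + [f"sbp_{band}_{win}" for band in ("0p5_4", "4_8", "8_13", "13_30", "30_48")
       for win in ("ste", "lte")]
    + [f"sef{x}_{win}" for x in (50, 90) for win in ("ste", "lte")]
)
assert len(FEATURE_CODES) == 34


def feature_column_names(channel_names):
    """Canonical ``<channel>__<code>`` column names, channel-major."""
    return [f"{ch}__{code}" for ch in channel_names for code in FEATURE_CODES]


@dataclass
class EEGRecord:
    """Multi-channel sampled EEG signal.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitude (arbitrary scale, nominally µV).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel_names: list = None
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValidationError("channel_names length must match channel count")
        if not np.isfinite(self.samples).all():
            raise ValidationError("record contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnnotationSet:
    """Seizure and artefact intervals in seconds, half-open ``[start, end)``."""

    seizures: list = field(default_factory=list)
    artefacts: list = field(default_factory=list)

    def __post_init__(self):
        self.seizures = [(float(a), float(b)) for a, b in self.seizures]
        self.artefacts = [(float(a), float(b)) for a, b in self.artefacts]
        for on, off in self.seizures + self.artefacts:
            if not on < off:
                raise ValidationError(
                    f"interval onset must precede offset, got ({on}, {off})")
        seiz = sorted(self.seizures)
        for (a0, b0), (a1, b1) in zip(seiz, seiz[1:]):
            if a1 < b0:
                raise ValidationError("seizure intervals must not overlap")

    def validate_within(self, duration_s: float) -> None:
        for on, off in self.seizures + self.artefacts:
            if on < 0 or off > duration_s + 1e-9:
                raise ValidationError(
                    f"interval ({on}, {off}) outside record of {duration_s} s")


@dataclass
class FeatureMatrix:
    """Instance-per-row feature table with timestamps and 4-state labels.

    One instance per 5-s tick; 204 columns for a 6-channel record
    (34 per-channel features).
    """

    values: np.ndarray
    timestamps: np.ndarray
    labels: np.ndarray
    column_names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D")
        n = self.values.shape[0]
        if len(self.timestamps) != n or len(self.labels) != n:
            raise ValidationError("timestamps/labels length must match row count")
        if self.values.shape[1] != len(self.column_names):
            raise ValidationError("column_names length must match column count")
        unknown = set(self.labels) - set(LABELS)
        if unknown:
            raise ValidationError(f"unknown labels: {sorted(unknown)}")
        if n > 1 and not (np.diff(self.timestamps) > 0).all():
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.column_names))
        df.insert(0, "time_s", self.timestamps)
        df.insert(1, "label", self.labels)
        return df


# ---------------------------------------------------------------------------
# EEG ASCII format


def read_eeg_ascii(path, fs: float, channel_names=None) -> EEGRecord:
    """Read a plain-ASCII EEG file (one row per sample, one column per channel).

    Raises :class:`FormatError` on ragged rows or non-numeric tokens,
    naming the offending line.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    sep = "," if "," in first else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         engine="c", dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed EEG ASCII file: {exc}") from exc
    if df.isna().any().any():
        line = int(df.index[df.isna().any(axis=1)][0]) + 1
        raise FormatError(f"{path}: ragged or non-numeric row at line {line}")
    samples = df.to_numpy().T
    if channel_names is not None and len(channel_names) != samples.shape[0]:
        raise FormatError(
            f"{path}: expected {len(channel_names)} channels, found {samples.shape[0]}")
    return EEGRecord(samples=samples, fs=fs, channel_names=list(channel_names)
                     if channel_names is not None else None)


def write_eeg_ascii(record: EEGRecord, path, fmt: str = "%.10g") -> None:
    np.savetxt(path, record.samples.T, fmt=fmt, delimiter=" ")


# ---------------------------------------------------------------------------
# Annotation sidecar


def read_annotations(path) -> AnnotationSet:
    """Parse the plain-text annotation sidecar.

    Each non-comment line is ``seizure <onset_s> <offset_s>`` or
    ``artefact <start_s> <end_s>``.
    """
    seizures, artefacts = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3 or parts[0] not in ("seizure", "artefact"):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"'seizure|artefact <start> <end>', got {raw!r}")
            try:
                start, end = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric interval") from exc
            (seizures if parts[0] == "seizure" else artefacts).append((start, end))
    return AnnotationSet(seizures=seizures, artefacts=artefacts)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# intervals in seconds from record start, half-open [start, end)\n")
        for on, off in annotations.seizures:
            fh.write(f"seizure {on:.6g} {off:.6g}\n")
        for a, b in annotations.artefacts:
            fh.write(f"artefact {a:.6g} {b:.6g}\n")


# ---------------------------------------------------------------------------
# Feature datasets


def write_feature_dataset(matrix: FeatureMatrix, path) -> None:
    """Write a feature dataset; ``.h5``/``.hdf5`` → exact binary, else CSV."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=matrix.values)
            f.create_dataset("timestamps", data=matrix.timestamps)
            f.create_dataset("labels", data=np.array(matrix.labels, dtype="S16"))
            f.attrs["column_names"] = json.dumps(list(matrix.column_names))
    else:
        matrix.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_feature_dataset(path) -> FeatureMatrix:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            timestamps = f["timestamps"][()]
            labels = [s.decode() for s in f["labels"][()]]
            column_names = json.loads(f.attrs["column_names"])
    else:
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "label" not in df.columns:
            raise FormatError(f"{path}: missing time_s/label columns")
        timestamps = df["time_s"].to_numpy(dtype=float)
        labels = df["label"].tolist()
        column_names = [c for c in df.columns if c not in ("time_s", "label")]
        values = df[column_names].to_numpy(dtype=float)
    bad = set(labels) - set(LABELS)
    if bad:
        raise FormatError(f"{path}: unknown label token(s) {sorted(bad)}")
    return FeatureMatrix(values=values, timestamps=np.asarray(timestamps),
                         labels=np.array(labels, dtype=object),
                         column_names=list(column_names))
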