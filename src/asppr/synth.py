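"""Synthetic annotated EEG records for end-to-end pipeline testing.

Each record emulates a one-hour, 6-channel "ictal file": an autoregressive
background with an alpha-band (10 Hz) oscillation, a single ~180 s seizure
with a 3–5x amplitude surge and a slow rhythmic component, and an optional
graded pre-ictal shift over the 5 minutes before onset.  Channels share a
single latent source plus independent noise, mimicking focal/extra-focal
similarity.  The generator is deterministic under a fixed seed.

The pre-ictal shift (``preictal_effect``) multiplies the alpha-band
component and adds a baseline offset, both ramping linearly from 0 at the
start of the pre-ictal window to full strength at onset; effect 0 makes
pre-ictal windows statistically indistinguishable from inter-ictal ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .eeg_io import AnnotationSet, EEGRecord, write_annotations, write_eeg_ascii
from .exceptions import ConfigurationError

#: AR(2) background coefficients (stable, low-pass, EEG-like 1/f slope)
_AR_COEFFS = (1.3, -0.4)
_ALPHA_HZ = 10.0   # background oscillation frequency
_ICTAL_HZ = 3.0    # rhythmic ictal component
_ICTAL_GAIN = 4.0  # amplitude surge during the seizure


@dataclass
class SynthConfig:
    """Parameters of one synthetic ictal file."""

    duration_s: float = 3600.0
    fs: float = 256.0
    n_channels: int = 6
    seizure_onset_s: float = 1800.0
    seizure_offset_s: float = 1980.0
    preictal_effect: float = 1.0
    noise_sd: float = 1.0
    artefact_intervals: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.seizure_onset_s < self.seizure_offset_s
                <= self.duration_s):
            raise ConfigurationError(
                f"need 0 <= onset < offset <= duration, got "
                f"({self.seizure_onset_s}, {self.seizure_offset_s}) in "
                f"{self.duration_s} s")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")
        if self.preictal_effect < 0:
            raise ConfigurationError("preictal_effect must be >= 0")
        for a, b in self.artefact_intervals:
            if not (0 <= a < b <= self.duration_s):
                raise ConfigurationError(f"bad artefact interval ({a}, {b})")


def _ar2(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    a1, a2 = _AR_COEFFS
    eps = rng.normal(0.0, sd, size=n)
    return lfilter([1.0], [1.0, -a1, -a2], eps)


def generate_record(config: SynthConfig):
    """Generate one annotated synthetic ictal file.

    Returns
    -------
    (EEGRecord, AnnotationSet)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    onset, offset = config.seizure_onset_s, config.seizure_offset_s

    # graded pre-ictal ramp: 0 at (onset - 300 s), 1 at onset
    pre_lo = max(onset - 300.0, 0.0)
    ramp = np.clip((t - pre_lo) / max(onset - pre_lo, 1e-9), 0.0, 1.0)
    ramp[t >= onset] = 0.0
    in_ictal = (t >= onset) & (t < offset)

    latent = _ar2(rng, n, config.noise_sd)
    channels = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        alpha = np.sin(2 * np.pi * _ALPHA_HZ * t + phase)
        # pre-ictal: multiplicative gain on the alpha band + a mean shift
        alpha = alpha * (1.0 + config.preictal_effect * ramp)
        x = (latent + _ar2(rng, n, config.noise_sd)
             + alpha + config.preictal_effect * ramp * config.noise_sd)
        # ictal: amplitude surge plus a low-frequency rhythmic component;
        # post-ictal: transient amplitude suppression recovering over 300 s
        surge = np.where(in_ictal, _ICTAL_GAIN, 1.0)
        post_frac = np.clip((t - offset) / 300.0, 0.0, 1.0)
        in_post = (t >= offset) & (t < offset + 300.0)
        surge = np.where(in_post, 0.5 + 0.5 * post_frac, surge)
        ict = np.where(in_ictal,
                       2.0 * _ICTAL_GAIN * np.sin(2 * np.pi * _ICTAL_HZ * t
                                                  + phase), 0.0)
        channels[ch] = x * surge + ict

    for a, b in config.artefact_intervals:
        i0, i1 = int(round(a * config.fs)), int(round(b * config.fs))
        channels[:, i0:i1] += 20.0 * config.noise_sd * (1 + rng.random())

    record = EEGRecord(samples=channels, fs=config.fs,
                       channel_names=[f"ch{i + 1}" for i in
                                      range(config.n_channels)])
    annotations = AnnotationSet(seizures=[(onset, offset)],
                                artefacts=list(config.artefact_intervals))
    return record, annotations


def generate_patient(config: SynthConfig, n_files: int, seed: int = None):
    """Generate ``n_files`` independent ictal files with derived sub-seeds."""
    if n_files < 1:
        raise ConfigurationError("n_files must be >= 1")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    out = []
    for child in ss.spawn(n_files):
        sub = SynthConfig(**{**asdict(config),
                             "seed": int(child.generate_state(1)[0] % (2 ** 31))})
        out.append(generate_record(sub))
    return out


def write_record(record: EEGRecord, annotations: AnnotationSet,
                 config: SynthConfig, prefix) -> None:
    """Write the ASCII record, annotation sidecar and a JSON provenance sidecar."""
    prefix = str(prefix)
    write_eeg_ascii(record, prefix + ".txt")
    write_annotations(annotations, prefix + ".ann")
    with open(prefix + ".json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
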