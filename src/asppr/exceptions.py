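"""Exception hierarchy for the asppr package."""


class AspprError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AspprError):
    """Invalid configuration (interval ordering, channel counts, ...)."""


class FormatError(AspprError):
    """Malformed on-disk input (ragged rows, unknown tokens, ...)."""


class ValidationError(AspprError):
    """Semantically invalid values (bad intervals, probabilities, ...)."""


class WindowError(AspprError):
    """A window is too short for the requested computation."""


class TrainingError(AspprError):
    """Model training cannot proceed (missing class, non-finite data, ...)."""


class PredictionError(AspprError):
    """Prediction-time contract violation (feature-count mismatch, ...)."""
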