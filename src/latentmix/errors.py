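"""Exception hierarchy used across the package."""


class LatentmixError(Exception):
    """Base class for package errors."""


class SchemaError(LatentmixError, ValueError):
    """Metadata table is missing required columns or has a malformed header."""


class ValidationError(LatentmixError, ValueError):
    """Inputs violate a documented precondition (labels, shapes, record kinds)."""


class StateError(LatentmixError, RuntimeError):
    """Operation requires a trained model or other state not yet established."""


class LeakageError(LatentmixError, RuntimeError):
    """Test-side information would reach a training set; always a hard failure."""


class TrainingError(LatentmixError, RuntimeError):
    """Optimization produced non-finite losses."""
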