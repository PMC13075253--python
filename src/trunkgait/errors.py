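"""Exception hierarchy shared across the pipeline."""


class TrunkGaitError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(TrunkGaitError):
    """A delimited-text file does not match the expected column schema."""


class UnitError(TrunkGaitError):
    """Declared units or sampling rate are inconsistent with the data."""


class SignalError(TrunkGaitError):
    """A signal violates a precondition (too short, zero variance, ...)."""


class NoLocomotionError(SignalError):
    """No step-frequency peak found in the locomotor band."""


class TruncationError(SignalError):
    """Fewer strides available than the requested truncation length."""


class ModelError(TrunkGaitError):
    """A statistical model could not be fitted (rank deficiency, ...)."""
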