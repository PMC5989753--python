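"""Package-wide exception types."""


class CogebmError(Exception):
    """Base class for all cogebm errors."""


class ConfigurationError(CogebmError):
    """Invalid configuration value (bad enum, negative rate, ...)."""


class PreprocessingError(CogebmError):
    """Imputation or residualization cannot proceed."""


class DegenerateDataError(CogebmError):
    """Input data carries no usable variation (e.g. all values identical)."""


class DirectionViolationError(CogebmError):
    """A fitted mixture places its abnormal component on the wrong side of
    the normal component for the biomarker's direction of decline."""
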