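"""Exception hierarchy shared across the pipeline stages."""


class CallspaceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CallspaceError):
    """A parameter is outside its admissible range (counts < 1, bad bands, ...)."""


class ValidationError(CallspaceError):
    """Input data violate a schema or a record invariant."""


class InsufficientDataError(CallspaceError):
    """Too few records/points to carry out the requested computation."""


class DegenerateDataError(CallspaceError):
    """Data are formally valid but carry no usable signal (zero variance, silent audio)."""


class DegenerateSignalError(DegenerateDataError):
    """An all-zero (silent) waveform was supplied to the feature extractor."""


class GridMismatchError(CallspaceError):
    """Two density regions do not share an identical grid specification."""
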