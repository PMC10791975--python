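"""Exception hierarchy shared by all modules."""


class FluorotrackError(Exception):
    """Base class for package errors."""


class ValidationError(FluorotrackError):
    """An input violates a documented invariant."""


class ParseError(FluorotrackError):
    """A file could not be parsed; the message names the offending record."""


class CalibrationError(FluorotrackError):
    """Calibration impossible (e.g. sphere label absent everywhere)."""


class BackendUnavailableError(FluorotrackError):
    """A segmentation backend's external dependency is missing."""


class ConfigurationError(FluorotrackError):
    """A configuration value is inconsistent or out of range."""
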