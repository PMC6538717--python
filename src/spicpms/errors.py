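"""Exception hierarchy shared across the pipeline stages."""


class SpicpmsError(Exception):
    """Base class for package-specific failures."""


class ValidationError(SpicpmsError, ValueError):
    """An input violated a documented precondition or type invariant."""


class DegenerateTraceError(SpicpmsError):
    """Thresholding could not retain the minimum number of background windows."""


class CalibrationError(SpicpmsError):
    """Calibration fit failed a quality requirement (e.g. non-positive slope)."""


class InconsistentReferenceError(SpicpmsError):
    """Transport-efficiency counts exceed the number of delivered particles."""


class InsufficientSignalError(SpicpmsError):
    """No particle events available where at least one is required."""


class NoLinearRegionError(SpicpmsError):
    """Every sample of a dilution series breaches the linearity tolerance."""


class UndefinedPartitionError(SpicpmsError):
    """Particle/ion partition requested for a sample with zero total analyte."""


class ParseError(SpicpmsError, ValueError):
    """A trace or report file failed to parse; the message names the line."""


class ConfigError(SpicpmsError, ValueError):
    """A run-configuration document is malformed or contains unknown keys."""
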