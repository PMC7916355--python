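"""Exception hierarchy with stable CLI exit codes."""


class SmartbrushError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(SmartbrushError):
    """Malformed input file (missing columns, bad header, bad values)."""

    exit_code = 3


class DimensionError(SmartbrushError):
    """Feature/model dimension mismatch."""

    exit_code = 4


class CalibrationError(SmartbrushError):
    """No qualifying rest segment for holder calibration."""

    exit_code = 5


class StreamOrderError(SmartbrushError):
    """Non-monotone timestamps in a stream."""

    exit_code = 6


class GimbalLockError(SmartbrushError):
    """Pitch too close to +/-90 deg for the arcsine roll formula."""

    exit_code = 7


class UndefinedAttitudeError(SmartbrushError):
    """Accelerometer reading with (near-)zero magnitude: attitude undefined."""

    exit_code = 8


class AlignmentError(SmartbrushError):
    """Attitude frames and raw stream not aligned."""

    exit_code = 9


class InputContractError(SmartbrushError):
    """An input violated a numeric contract (e.g. not a probability vector)."""

    exit_code = 10


class OutOfRangeError(SmartbrushError):
    """Sensor value outside its physically valid range."""

    exit_code = 11


class ConfigError(SmartbrushError):
    """Invalid or incomplete configuration."""

    exit_code = 12


class EvaluationError(SmartbrushError):
    """Fitness evaluation returned a non-finite value."""

    exit_code = 13


class MigrationError(SmartbrushError):
    """Target data unusable for model migration."""

    exit_code = 14
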