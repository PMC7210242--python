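"""Exception hierarchy for the fluoromargin pipeline."""


class FluoromarginError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FluoromarginError):
    """Invalid configuration value; the message names the offending field."""


class InputError(FluoromarginError):
    """Invalid input to an operation (bad value, shape mismatch, empty input)."""


class CalibrationError(FluoromarginError):
    """Threshold calibration cannot proceed (single-class data, missing baseline)."""


class AdjudicationError(FluoromarginError):
    """Inconsistent device-reading / histopathology / action combination."""


class ParseError(FluoromarginError):
    """A file on disk could not be parsed; the message names the file."""
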