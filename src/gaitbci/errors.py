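"""Exception hierarchy shared across the package."""


class GaitBCIError(Exception):
    """Base class for all package errors."""


class FormatError(GaitBCIError, ValueError):
    """A file or data structure violates its declared format."""


class RangeError(GaitBCIError, ValueError):
    """An interval or index falls outside the data it addresses."""


class ParameterError(GaitBCIError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateDataError(GaitBCIError, ValueError):
    """Input data are degenerate for the requested computation
    (constant sequences, single-class calibration data, ...)."""
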