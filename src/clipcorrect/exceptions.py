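"""Exception hierarchy.

All errors raised by the library derive from :class:`ClipcorrectError`, so
callers (and the CLI) can catch one type and translate it into a nonzero
exit status with a message.
"""


class ClipcorrectError(Exception):
    """Base class for all errors raised by clipcorrect."""


class ConfigurationError(ClipcorrectError):
    """Invalid acquisition or run configuration (e.g. n_scans < 2)."""


class StructuralError(ClipcorrectError):
    """Structurally inconsistent inputs (mismatched frame shapes, masks)."""


class InsufficientDataError(ClipcorrectError):
    """Not enough observations for the requested statistic."""


class InfeasibleError(ClipcorrectError):
    """Estimation impossible in principle: every scan value is censored."""


class EstimationError(ClipcorrectError):
    """Numerical estimation failed (no root within the search bounds)."""


class CalibrationError(ClipcorrectError):
    """Instrument standardization failed or is unreliable."""


class CrossValidationError(ClipcorrectError):
    """Cross-validation cannot be set up (too few parameter groups)."""


class GenerationError(ClipcorrectError):
    """Synthetic fixture cannot be generated under the given constraints."""


class FormatError(ClipcorrectError):
    """A file could not be parsed or has an unsupported layout."""
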