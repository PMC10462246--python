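"""Exception hierarchy shared across the package."""


class PredoseError(Exception):
    """Base class for all package errors."""


class FormatError(PredoseError, ValueError):
    """An input file does not parse or lacks required columns."""


class ValidationError(PredoseError, ValueError):
    """Parsed input violates a physical or structural invariant."""


class FitError(PredoseError, RuntimeError):
    """Nonlinear regression could not produce a usable result."""
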