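"""Exception types shared across the package."""


class Sig32Error(Exception):
    """Base class for all package errors."""


class InvalidDesignError(Sig32Error, ValueError):
    """A simulation design violates its invariants."""


class InputError(Sig32Error, ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Feature (gene) order does not match the model's expected order."""


class CoverageError(InputError):
    """Too few signature genes present in an expression matrix."""


class FitError(Sig32Error, RuntimeError):
    """A model fit failed or did not converge."""


class ParseError(Sig32Error, ValueError):
    """A file could not be parsed; message carries the offending location."""
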