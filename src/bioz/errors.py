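"""Exception hierarchy shared across the package."""


class BiozError(Exception):
    """Base class for all package errors."""


class ValidationError(BiozError, ValueError):
    """A parameter or data structure violates a declared invariant."""


class RangeError(BiozError):
    """A requested operating point falls outside the instrument's range."""


class FitError(BiozError):
    """A model fit failed to converge or the model is unidentifiable."""


class ParseError(BiozError):
    """A file could not be parsed; the message names the offending row."""
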