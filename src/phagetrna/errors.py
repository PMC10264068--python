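"""Exception types shared across the package."""


class PhagetrnaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhagetrnaError, ValueError):
    """An input file violates its declared format."""


class ValidationError(PhagetrnaError, ValueError):
    """Well-formed input carries values that violate a domain constraint."""


class DegenerateInputError(PhagetrnaError, ValueError):
    """A statistical routine received input on which its result is undefined
    (e.g. zero variance in both groups of a t-test)."""
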