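"""Exception hierarchy shared across the package."""


class EcgdxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EcgdxError, ValueError):
    """A file did not parse as the expected on-disk format."""


class EmptyInputError(FormatError):
    """An input file or sequence contained no usable data."""


class LeadNotFoundError(EcgdxError, KeyError):
    """The requested lead is absent from a record."""


class ParameterError(EcgdxError, ValueError):
    """A configuration value violates its documented constraints."""


class InputTooShortError(EcgdxError, ValueError):
    """The input sequence is shorter than the operation requires."""


class InsufficientPeaksError(InputTooShortError):
    """Fewer R peaks than the operation requires."""


class InsufficientSegmentsError(InputTooShortError):
    """Fewer heart-beat segments than one group requires."""


class DivergenceError(EcgdxError, RuntimeError):
    """Numerical training diverged (NaN/inf loss)."""
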