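"""Exception hierarchy shared across the package."""


class EigenfluorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EigenfluorError, ValueError):
    """An image file or array has an unsupported format or layout."""


class GeometryError(EigenfluorError, ValueError):
    """Channel images that must share dimensions do not."""


class ValidationError(EigenfluorError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(EigenfluorError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class DegenerateInputError(EigenfluorError, ValueError):
    """Input is valid in shape but carries no usable signal (e.g. zero variance)."""
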