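"""Exception hierarchy shared across the package."""


class ClemQuantError(Exception):
    """Base class for all package errors."""


class FormatError(ClemQuantError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(ClemQuantError):
    """An input object violates a documented invariant."""


class GeometryError(ClemQuantError):
    """A geometric computation received degenerate input."""


class AnalysisError(ClemQuantError):
    """An analysis step cannot produce a defined result."""
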