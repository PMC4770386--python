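"""Exception hierarchy."""


class ProteoturnError(Exception):
    """Base class for all package errors."""


class ValidationError(ProteoturnError):
    """Invalid user input (bad residue code, malformed table, bad config)."""


class DegenerateFitError(ProteoturnError):
    """Curve fitting impossible: constant data or too few points."""


class NoCrossingError(ProteoturnError):
    """The degradation profile never reaches 50% (ascending or flat)."""


class SchemaError(ValidationError):
    """A required column is missing or has the wrong type."""
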