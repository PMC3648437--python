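"""Exception and warning types shared across the package."""


class SeroArrayError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeroArrayError):
    """A required element of an input file is missing or malformed."""


class RowParseError(FormatError):
    """A data row of an input file could not be parsed; carries the line number."""


class DimensionError(SeroArrayError):
    """Objects being combined have incompatible shapes."""


class ValidationError(SeroArrayError):
    """An input violates a documented precondition."""


class CytobandParseError(SeroArrayError):
    """A cytogenetic band string does not match the chromosome+arm+band grammar."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at its iteration cap; the last iterate is returned."""


class SeparationWarning(UserWarning):
    """Complete separation detected during a logistic fit."""
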