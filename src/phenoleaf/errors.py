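"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems -> 2, weather
coverage problems -> 3.
"""


class PhenoleafError(Exception):
    """Base class for all package errors."""


class DataValidationError(PhenoleafError):
    """Input data violates an invariant (bad DOY, negative precip, ...)."""


class CoverageError(PhenoleafError):
    """Weather series does not cover a required date range."""


class DomainError(PhenoleafError):
    """Argument outside the supported physical domain (rh, polar latitude)."""


class InvalidParameterError(PhenoleafError):
    """Model parameter vector violates an internal constraint."""


class DegenerateInputError(PhenoleafError):
    """Statistic undefined for the given input (e.g. constant vector)."""
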