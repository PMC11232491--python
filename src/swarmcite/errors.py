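"""Typed exceptions shared across the pipeline.

Every parser raises :class:`InputFormatError` on malformed input, every
parameter check raises :class:`ConfigurationError`, and numerical
degeneracies (zero profiles, too few items to cluster) raise the dedicated
classes below so callers can distinguish bad data from bad configuration.
"""


class SwarmciteError(Exception):
    """Base class for all package errors."""


class InputFormatError(SwarmciteError):
    """A file does not conform to its declared format.

    Parameters
    ----------
    message:
        Human-readable description of the violation.
    line:
        1-based line number of the offending record, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(SwarmciteError):
    """A parameter or configuration value is invalid."""


class DegenerateInputError(SwarmciteError):
    """Input is structurally valid but too degenerate for the operation."""


class UndefinedSimilarityError(SwarmciteError):
    """Cosine similarity requested for a zero vector."""


class UnknownProteinError(SwarmciteError, KeyError):
    """A protein symbol was looked up in a network that does not contain it."""
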