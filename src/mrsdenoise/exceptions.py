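"""Package-wide exception types."""


class MrsDenoiseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MrsDenoiseError, ValueError):
    """An argument violates an operation's precondition."""


class ParseError(MrsDenoiseError, ValueError):
    """A text input (peak table, spectrum file) could not be parsed."""


class IntegrityError(MrsDenoiseError, RuntimeError):
    """A stored dataset or checkpoint failed a consistency/checksum check."""


class UndefinedCorrelationError(MrsDenoiseError, ValueError):
    """Pearson correlation requested for a zero-variance signal."""
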