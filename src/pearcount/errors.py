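"""Exception hierarchy shared across the toolkit."""


class PearcountError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PearcountError, ValueError):
    """A text file line could not be parsed; the message names the line."""


class ValidationError(PearcountError, ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(PearcountError, ValueError):
    """An operation was invoked with an inconsistent configuration."""


class SequencingError(PearcountError, RuntimeError):
    """Frames were presented to the online tracker out of order."""


class NumericalError(PearcountError, ArithmeticError):
    """A filter covariance lost positive-definiteness."""


class ConsistencyError(PearcountError, ValueError):
    """Cross-referenced records disagree (e.g. a counted id with no track)."""
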