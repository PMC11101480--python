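"""Exception hierarchy for emtridge."""


class EmtridgeError(Exception):
    """Base class for all package errors."""


class ConfigError(EmtridgeError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(EmtridgeError, ValueError):
    """Input violates a documented precondition."""


class ParseError(EmtridgeError, ValueError):
    """Malformed input file; the message localises the problem."""


class CoverageError(EmtridgeError, ValueError):
    """Too few model genes present in the target expression matrix."""


class UndefinedStatisticError(EmtridgeError, ValueError):
    """A statistic is mathematically undefined for the given input
    (e.g. Cohen's kappa when chance agreement equals 1)."""
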