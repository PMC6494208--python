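"""Exception taxonomy: configuration vs. data vs. numerical problems."""


class NumdecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NumdecodeError, ValueError):
    """An impossible or inconsistent configuration (exit code 2 in the CLI)."""


class DataError(NumdecodeError, ValueError):
    """Inputs that violate a precondition (shape/length/label mismatches)."""


class NumericalError(NumdecodeError, ArithmeticError):
    """Degenerate numerics: zero variance, non-PSD targets, |r| = 1."""
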