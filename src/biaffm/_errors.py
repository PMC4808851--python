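"""Exception hierarchy shared across the package.

Two failure classes are distinguished because they map to different
command-line exit codes: malformed or physically impossible input (exit 2)
versus data that is well-formed but does not satisfy the preconditions of a
statistical procedure, e.g. zero variance or too few observations (exit 3).
"""


class BiaffmError(Exception):
    """Base class for all package-specific errors."""


class InputValidationError(BiaffmError):
    """Raised when input data or configuration violates an invariant."""


class StatisticalError(BiaffmError):
    """Raised when a statistical procedure's preconditions are not met."""
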