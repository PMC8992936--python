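"""Exception hierarchy.

Validation errors map to CLI exit code 2, numerical/convergence failures
to exit code 3.
"""


class PosequivError(Exception):
    """Base class for package errors."""


class ValidationError(PosequivError, ValueError):
    """Invalid input data or configuration."""


class ConvergenceError(PosequivError, RuntimeError):
    """A numerical procedure failed to converge."""
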