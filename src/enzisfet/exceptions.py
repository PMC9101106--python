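"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage 2, data 3,
convergence 4) so shell pipelines can tell a bad invocation from a bad
dataset from a failed fit.
"""


class EnzIsfetError(Exception):
    """Base class for all package errors."""


class DomainError(EnzIsfetError, ValueError):
    """A physical quantity is outside its valid domain (pH, concentration, ...)."""


class UsageError(EnzIsfetError, ValueError):
    """An argument combination that can never be valid (empty grid, negative SD, ...)."""


class DataError(EnzIsfetError, ValueError):
    """The data cannot support the requested operation (degenerate column, tiny stratum, ...)."""


class ConvergenceError(EnzIsfetError, RuntimeError):
    """Training produced a non-finite loss; usually the learning rate is too large."""
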