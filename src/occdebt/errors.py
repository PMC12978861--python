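"""Exception hierarchy shared across the package."""


class OccdebtError(Exception):
    """Base class for all package errors."""


class StudyValidationError(OccdebtError, ValueError):
    """Raised when study data violate a schema or domain invariant.

    The message always identifies the offending site / season / visit
    (or file row and column) so bad cells can be located in the source CSVs.
    """


class ConvergenceError(OccdebtError, RuntimeError):
    """Raised when an optimisation fails and the caller demanded convergence."""


class BootstrapError(OccdebtError, RuntimeError):
    """Raised when too many bootstrap replicates fail to refit."""
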