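"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: ConfigError -> 2,
DataError -> 3, NumericalError -> 4.
"""


class VisCSFError(Exception):
    """Base class for all package errors."""


class DomainError(VisCSFError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ClippingError(DomainError):
    """Requested display rendering would clip against the 8-bit range."""


class ConfigError(VisCSFError):
    """Invalid or unparseable run configuration."""


class DataError(VisCSFError):
    """Malformed or insufficient input data (CSV schema, frame mismatch...)."""


class NumericalError(VisCSFError):
    """A numerical procedure failed (singularity, non-convergence)."""


class RankDeficiencyError(NumericalError):
    """Unregularized least-squares system is rank deficient."""


class DegenerateFitError(NumericalError):
    """Fit is undefined because the response carries no variance."""
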