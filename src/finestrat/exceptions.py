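"""Exception hierarchy for finestrat.

All package errors derive from :class:`FinestratError` so callers can catch
one base class; subclasses mirror the failure modes of the design/estimator
contracts (invalid designs, degenerate normalizing constants, enumeration
limits, file-schema problems).
"""


class FinestratError(Exception):
    """Base class for all finestrat errors."""


class InvalidDesignError(FinestratError):
    """A sample violates the sampling-design contract (e.g. pi <= 0)."""


class InfeasibleDesignError(FinestratError):
    """Requested per-stratum sample sizes cannot be drawn (n_i > N_i)."""


class CannotCollapseError(FinestratError):
    """Too few strata to form pseudo-strata (H < 2)."""


class CannotBootstrapError(FinestratError):
    """Total sample too small to form bootstrap pseudo-strata."""


class DegenerateBandwidthError(FinestratError):
    """Kernel window so narrow that every stratum only sees itself (c_d = 0)."""


class DegenerateCorrectorError(FinestratError):
    """Bootstrap bias correctors sum to zero; weights cannot be normalized."""


class DegenerateNormalizerError(FinestratError):
    """The bootstrap normalizing constant c_b is exactly zero."""


class UndefinedRescaleError(FinestratError):
    """Mean function is constant on [0, 1]; the [0, 2] rescale is undefined."""


class EnumerationLimitError(FinestratError):
    """Exact enumeration would exceed the hard combinatorial cap."""


class ConfigError(FinestratError):
    """Invalid simulation or run configuration."""


class SchemaError(FinestratError):
    """Input file is missing required columns or is internally inconsistent."""


class ParseError(FinestratError):
    """A value in an input file could not be parsed."""


class EmptyAfterFilterError(FinestratError):
    """Preprocessing filters removed every record."""
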