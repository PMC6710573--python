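"""Exception types shared across the package."""


class MaramsgError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MaramsgError):
    """An input table is structurally malformed (e.g. a required column is missing)."""


class ReferentialError(MaramsgError):
    """A foreign-key style reference between input tables cannot be resolved."""


class ValidationError(MaramsgError):
    """A value in otherwise well-formed input violates a domain invariant."""


class ConfigurationError(MaramsgError):
    """A user-supplied configuration object is internally inconsistent."""


class EmptyDatasetError(MaramsgError):
    """A filtering or partitioning step produced a dataset with no social units."""


class InfeasibleRandomizationError(MaramsgError):
    """The constrained randomization has no valid arrangement for this dataset."""


class EnumerationCapError(MaramsgError):
    """Exhaustive enumeration of the null space would exceed the configured cap."""


class UndefinedStatisticError(MaramsgError):
    """A requested statistic is not measurable on this dataset (sentinel input)."""
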