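"""Exception hierarchy shared across the package."""


class DiatomSeasonError(Exception):
    """Base class for package errors."""


class SpecificationError(DiatomSeasonError, ValueError):
    """Invalid model specification (periods, harmonics, TVP kinds, levels)."""


class OrderingError(DiatomSeasonError, ValueError):
    """Time stamps not strictly increasing, or a non-positive gap."""


class NumericalConditioningError(DiatomSeasonError, RuntimeError):
    """Singular or non-finite quantity in the filter/smoother recursions."""


class EstimationError(DiatomSeasonError, RuntimeError):
    """Hyperparameter search failed to converge.

    Carries ``best`` (the best parameter values found) so callers can
    inspect or reuse them.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UnderdeterminedFitError(DiatomSeasonError, ValueError):
    """Fewer observations than effective model degrees of freedom."""


class EmptySampleError(DiatomSeasonError, ValueError):
    """A count-matrix row with zero total valves."""


class TaxonLookupError(DiatomSeasonError, KeyError):
    """A taxon code absent from the count matrix or trait table."""


class NoIndexError(DiatomSeasonError, ValueError):
    """No counted taxon has trait coverage, so no index can be formed."""


class DegenerateReferenceError(DiatomSeasonError, ValueError):
    """Expected index equals the top of the scale; EQR undefined."""


class DomainError(DiatomSeasonError, ValueError):
    """Input outside the mathematical domain of a transform."""


class NoDataError(DiatomSeasonError, ValueError):
    """Requested window lies before any sensor record."""


class CoverageError(DiatomSeasonError, ValueError):
    """All requested windows fail the minimum-coverage threshold."""


class ConfigError(DiatomSeasonError, ValueError):
    """Pipeline configuration failed validation."""
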