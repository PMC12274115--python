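"""Exception hierarchy shared across the pipeline stages."""


class AidImpactError(Exception):
    """Base class for all package errors."""


class SchemaError(AidImpactError):
    """A table is missing required columns or has an incompatible layout."""


class IntegrityError(AidImpactError):
    """A panel violates a structural invariant (duplicates, too few units)."""


class DegenerateDistributionError(AidImpactError):
    """A distribution has no spread where quantile cut points are required."""


class ConfigError(AidImpactError):
    """An invalid configuration value or unknown configuration key."""


class EstimationError(AidImpactError):
    """The iterative fitter failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankError(AidImpactError):
    """Perfectly collinear design; names the aliased columns."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = list(aliased)


class VarianceError(AidImpactError):
    """A variance matrix is unusable (too few clusters, not PSD)."""


class ExtrapolationError(AidImpactError):
    """Too little history to project a covariate forward."""


class ScenarioError(AidImpactError):
    """A funding scenario does not cover the projection horizon."""


class ForecastError(AidImpactError):
    """A projected quantity is undefined (e.g. zero baseline deaths)."""


class SeparationError(AidImpactError):
    """Perfect separation in the propensity model; names the covariate."""

    def __init__(self, message, covariate=None):
        super().__init__(message)
        self.covariate = covariate


class EmptyMatchError(AidImpactError):
    """No control fell within the caliper of any treated unit."""
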