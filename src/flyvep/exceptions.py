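"""Exception hierarchy for the SSVEP pipeline.

Every anticipated failure mode raises a subclass of :class:`FlyVEPError`
so callers can distinguish pipeline errors from programming errors.
"""


class FlyVEPError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(FlyVEPError):
    """A genotype specification violates its invariants (e.g. gain <= 0)."""


class InvalidDesignError(FlyVEPError):
    """A cohort design is inconsistent (e.g. duplicate genotype names)."""


class ConfigurationError(FlyVEPError):
    """A run configuration is invalid (Nyquist violation, bad class map...)."""


class InsufficientDataError(FlyVEPError):
    """Not enough samples/windows/bins to perform the requested operation."""


class ShapeError(FlyVEPError):
    """Inputs have inconsistent shapes."""


class FrequencyGridError(FlyVEPError):
    """A requested analysis frequency does not fall on the spectral bin grid."""


class IncompleteFlyError(FlyVEPError):
    """A fly is missing recordings for one or more stimulus conditions."""

    def __init__(self, fly_id, missing_conditions):
        self.fly_id = fly_id
        self.missing_conditions = list(missing_conditions)
        super().__init__(
            f"fly {fly_id!r} is missing {len(self.missing_conditions)} "
            f"condition(s): {self.missing_conditions}"
        )


class EmptyTableError(FlyVEPError):
    """An operation received an empty cohort or feature table."""


class SingularCovarianceError(FlyVEPError):
    """The (regularized) pooled covariance is singular.

    Either increase gamma, or fit with ``singular='pinv'`` to use a
    pseudo-inverse with explicit rank logging (raw-data mode).
    """


class DegenerateClassError(FlyVEPError):
    """A class has fewer than the minimum required members."""


class NoFeaturesRetainedError(FlyVEPError):
    """The delta threshold eliminated every feature."""


class InvalidInputError(FlyVEPError):
    """A sample to classify contains non-finite values."""


class OptimizationFailureError(FlyVEPError):
    """No (gamma, delta) candidate produced a valid fit."""


class LabellingError(FlyVEPError):
    """An unknown genotype label was encountered."""


class UndefinedCorrelationError(FlyVEPError):
    """Correlation distance is undefined for a constant mean vector."""


class SchemaError(FlyVEPError):
    """A feature CSV or config file does not match the expected schema."""


class ValidationError(FlyVEPError):
    """A value failed validation (NaN amplitude, missing seed...)."""
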