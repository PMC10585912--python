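"""Exception hierarchy for longplasmode."""


class LongPlasmodeError(Exception):
    """Base class for all package errors."""


class SchemaError(LongPlasmodeError):
    """The data table does not match the variable specification."""


class MissingDataError(LongPlasmodeError):
    """The data contain missing values, which are not supported."""


class DistributionError(LongPlasmodeError):
    """A column's values are incompatible with its declared distribution."""


class UnsupportedCodingError(LongPlasmodeError):
    """The requested exposure-pattern coding is not defined for this K."""


class FittingError(LongPlasmodeError):
    """A conditional model failed to fit (non-convergence, separation)."""


class DegenerateModelError(LongPlasmodeError):
    """A model target is constant, so no conditional law can be learned."""


class CompatibilityError(LongPlasmodeError):
    """A generator set and a cohort were built from different specs."""


class PositivityError(LongPlasmodeError):
    """A fitted exposure probability of 0 or 1 was encountered."""


class EstimationError(LongPlasmodeError):
    """An estimator could not produce estimates (e.g. missing category)."""


class ConfigError(LongPlasmodeError):
    """Invalid configuration (design, regimes, CLI arguments)."""
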