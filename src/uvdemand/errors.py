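"""Exception hierarchy for the unit-value demand pipeline."""


class UVDemandError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UVDemandError):
    """The run configuration is invalid (missing column, unknown year, bad key)."""


class ValidationError(UVDemandError):
    """Input records violate the data contract (negative expenditure etc.)."""


class DataInconsistencyError(ValidationError):
    """Mutually inconsistent fields, e.g. positive spending with zero quantity."""


class GenerationError(UVDemandError):
    """A synthetic-truth parameter set produces invalid survey records."""


class EstimationError(UVDemandError):
    """An estimation stage cannot proceed (singular design, non-positive
    corrected variance, too many failed bootstrap replicates)."""
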