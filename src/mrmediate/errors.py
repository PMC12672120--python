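"""Exception hierarchy shared across the package."""


class MrmediateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MrmediateError):
    """A file does not conform to the expected tabular layout."""


class RowValidationError(MrmediateError):
    """One or more rows carry values that cannot be parsed.

    Carries the offending variant identifiers in ``variant_ids``.
    """

    def __init__(self, message: str, variant_ids: list[str] | None = None):
        super().__init__(message)
        self.variant_ids = variant_ids or []


class HarmonizationError(MrmediateError):
    """Exposure and outcome summary statistics cannot be aligned."""


class ContractError(MrmediateError):
    """An input violates a documented precondition (e.g. LD matrix coverage)."""


class InsufficientInstrumentsError(MrmediateError):
    """Too few instruments for the requested estimator."""


class EstimationError(MrmediateError):
    """A fit is degenerate (e.g. rank-deficient regression design)."""


class MediationStepError(MrmediateError):
    """A step of the three-step mediation workflow has no valid instruments."""


class ConfigError(MrmediateError):
    """A run configuration is malformed."""
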