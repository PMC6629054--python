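"""Package exception hierarchy."""


class AkiPredictError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AkiPredictError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(AkiPredictError):
    """An input table violates the documented schema."""


class SeparationError(AkiPredictError):
    """Complete or quasi-complete separation in a logistic fit."""

    def __init__(self, covariates, message=None):
        self.covariates = list(covariates)
        super().__init__(
            message
            or "complete separation detected; offending covariate(s): "
            + ", ".join(self.covariates)
        )


class SingularDesignError(AkiPredictError):
    """Rank-deficient design matrix; message lists collinear columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or "singular design matrix; collinear column(s): " + ", ".join(self.columns)
        )
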