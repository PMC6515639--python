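"""Exception hierarchy for mvtlogit."""


class MvtlogitError(Exception):
    """Base class for package errors."""


class SchemaError(MvtlogitError, ValueError):
    """A required column is missing or misnamed in an input table."""


class ValidationError(MvtlogitError, ValueError):
    """An input value violates a model invariant (e.g., non-binary outcome)."""


class UnsupportedExposureError(MvtlogitError, ValueError):
    """The high-dose / no-CRT combination, absent from the study design."""


class ConfigurationError(MvtlogitError, ValueError):
    """An unknown option tag (transform, covariate set, variant...)."""


class IntegrationError(MvtlogitError, RuntimeError):
    """Requested orthant-probability accuracy not reached within the cap."""

    def __init__(self, message: str, achieved_error: float):
        super().__init__(message)
        self.achieved_error = achieved_error


class DiagnosticError(MvtlogitError, ValueError):
    """A convergence diagnostic is undefined for the given chain."""
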