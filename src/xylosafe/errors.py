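"""Exception hierarchy shared across the package."""


class XylosafeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XylosafeError):
    """Invalid study or pipeline configuration."""


class DomainError(XylosafeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InputError(XylosafeError, ValueError):
    """Malformed or inconsistent input data (schema, units, integrity)."""


class FitError(XylosafeError):
    """Nonlinear or mixed-model fit failed after all restarts.

    Carries a ``diagnostics`` dict with the starting values, the final
    residual norm and the optimizer status of every attempt.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
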