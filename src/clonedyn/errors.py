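"""Exception hierarchy for the clonedyn pipeline."""


class CloneDynError(Exception):
    """Base class for all clonedyn errors."""


class ConfigError(CloneDynError):
    """Invalid cohort or run configuration."""


class InputError(CloneDynError):
    """Malformed input table (negative counts, alt > total, duplicate rows...)."""


class InsufficientDataError(CloneDynError):
    """Too few observations to fit the requested model."""


class SeparationError(CloneDynError):
    """Logistic fit is degenerate (perfect separation or single-class outcome)."""


class ConvergenceError(CloneDynError):
    """Mixed-model estimation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
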