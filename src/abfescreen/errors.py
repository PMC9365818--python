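"""Exception hierarchy for the screening pipeline."""


class AbfeScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(AbfeScreenError):
    """An object or argument violates a documented invariant."""


class SchemaError(AbfeScreenError):
    """A table is missing a required column or has an unusable header."""


class FormatError(AbfeScreenError):
    """A file is malformed (bad XYZ header, unparseable numeric, ...)."""


class ConvergenceError(AbfeScreenError):
    """An iterative estimator failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedMetricError(AbfeScreenError):
    """A metric is undefined for the given input (e.g. single-class ROC)."""
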