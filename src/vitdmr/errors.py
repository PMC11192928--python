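"""Exception hierarchy shared across the package."""


class VitdmrError(Exception):
    """Base class for package errors."""


class ValidationError(VitdmrError, ValueError):
    """Invalid input values or configuration."""


class PanelError(ValidationError):
    """Invalid SNP instrument panel."""


class SeparationError(VitdmrError):
    """Logistic regression detected (quasi-)complete separation."""


class DegenerateInputError(ValidationError):
    """Zero-variance or otherwise degenerate input to an estimator."""


class SeasonalSpreadError(ValidationError):
    """Not enough seasonal spread to fit the cosinor model."""


class WeakFirstStageError(VitdmrError):
    """First-stage coefficient is zero or unusable for a ratio estimate."""


class StageError(VitdmrError):
    """A pipeline stage failed."""
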