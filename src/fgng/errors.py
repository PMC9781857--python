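"""Exception hierarchy for the fgng package."""


class FgngError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FgngError, ValueError):
    """An input fraction or probability lies outside its mathematical domain."""


class ConfigurationError(FgngError):
    """Invalid static configuration (unknown element, bad fragment model, ...)."""


class CalibrationError(FgngError):
    """The standard curve cannot be fitted or used."""


class MeasurementError(FgngError):
    """A measured value is physically impossible or unusable."""


class DesignError(FgngError):
    """The factorial design is degenerate (empty cell, no residual df, ...)."""


class DegenerateDataError(FgngError):
    """Data admit no meaningful statistic (e.g. zero variance with unequal means)."""


class PipelineError(FgngError):
    """End-to-end run failed; message carries row-level context where known."""
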