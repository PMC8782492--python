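"""Exception hierarchy shared across the pipeline."""


class SpringPulseError(Exception):
    """Base class for all package errors."""


class FormatError(SpringPulseError):
    """A file could not be parsed (malformed date, unknown dialect, ...)."""


class IntegrityError(SpringPulseError):
    """Parsed data violate an invariant (duplicate dates, end before start, ...)."""


class IncompleteYearError(SpringPulseError):
    """A calendar year has gaps too long for the configured gap policy."""


class InsufficientDataError(SpringPulseError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(SpringPulseError):
    """The statistic is undefined for this input (zero variance, ...)."""


class AssemblyError(SpringPulseError):
    """Design-matrix assembly failed (missing covariate years or columns)."""


class SeparationError(SpringPulseError):
    """The binary response has a single class; the logistic fit is degenerate."""


class FitError(SpringPulseError):
    """A model fit failed (flat curve, zero-variance covariate, ...)."""


class ScenarioError(SpringPulseError):
    """Synthetic-scenario parameters are inconsistent."""


class ConfigError(SpringPulseError):
    """Pipeline configuration is invalid or references missing inputs."""


class StageError(SpringPulseError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
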