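"""Exception hierarchy shared by all pipeline stages."""


class AgemarkersError(Exception):
    """Base class for all package errors."""


class SchemaError(AgemarkersError):
    """A tabular input is missing a mandatory column or declared feature."""


class TableParseError(AgemarkersError):
    """A cell in a tabular input cannot be interpreted (carries row index)."""


class MergeError(AgemarkersError):
    """A phenotype record has no matching life-expectancy entry."""


class ValidationError(AgemarkersError):
    """A value violates a domain invariant (e.g. percentage outside [0, 100])."""


class DegenerateFeatureError(AgemarkersError):
    """A feature is constant or has too little spread to standardize."""


class InsufficientDataError(AgemarkersError):
    """Too few complete observations for the requested fit."""


class RankDeficiencyError(AgemarkersError):
    """The design is rank deficient (e.g. all records at a single age)."""


class CollinearityError(AgemarkersError):
    """Covariates passed to a joint fit are linearly dependent."""

    def __init__(self, columns, message=None):
        self.columns = tuple(columns)
        super().__init__(message or f"collinear covariates: {', '.join(self.columns)}")


class ConfigurationError(AgemarkersError):
    """A configuration value is invalid or infeasible."""


class AnnotationError(AgemarkersError):
    """An effect annotation contradicts the classification it should support."""


class FitError(AgemarkersError):
    """A model fit failed to converge (non-separation cause)."""


class ChartSpecError(AgemarkersError):
    """Ordering and cell inputs of a chart do not describe the same features."""


class PipelineError(AgemarkersError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
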