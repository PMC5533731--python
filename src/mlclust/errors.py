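"""Exception hierarchy shared across the package."""


class MlclustError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MlclustError):
    """Input table violates the declared descriptor schema (missing columns, empty file)."""


class ParseError(MlclustError):
    """A cell or row of an input table could not be interpreted."""


class ConfigurationError(MlclustError):
    """A parameter or descriptor request is invalid for the data at hand."""


class EvaluationError(MlclustError):
    """A rule or classifier was asked about a descriptor the instance does not provide."""


class ValidationError(MlclustError):
    """A cross-cohort validation precondition (e.g. disjoint cohort tags) failed."""


class UndefinedStatistic(MlclustError):
    """A test statistic is undefined for the given input (e.g. a zero margin)."""
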