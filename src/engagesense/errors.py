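"""Exception types shared across the pipeline."""


class EngageSenseError(Exception):
    """Base class for package errors."""


class ConfigurationError(EngageSenseError):
    """A pattern table, config file, or parameter block is malformed."""


class InvalidArgumentError(EngageSenseError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedFeatureError(EngageSenseError):
    """A frame has too few samples for the requested feature; the frame
    is excluded from downstream sign analysis."""


class EmptyOutputError(EngageSenseError):
    """A cleaning step rejected every sample."""


class AlignmentError(EngageSenseError):
    """Streams cannot be harmonized onto a common clock."""


class UndefinedResultError(EngageSenseError):
    """A statistic has no retained observations (N = 0)."""
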