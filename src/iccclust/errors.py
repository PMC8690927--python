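"""Exception types shared across the package."""


class IccclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IccclustError, ValueError):
    """An input file does not conform to the expected layout."""


class ValidationError(IccclustError, ValueError):
    """Invalid values were passed to an operation."""


class UndefinedPairError(IccclustError):
    """A gene pair has no pairwise-complete samples, so its 2x2 table is undefined."""


class UndefinedMetricError(IccclustError):
    """A statistic is undefined for the given inputs (e.g. single-class truth)."""


class EmptyOverlapError(IccclustError):
    """A gene signature shares no genes with the expression matrix."""


class ConvergenceError(IccclustError):
    """A model fit failed to converge (e.g. a degenerate covariate)."""
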