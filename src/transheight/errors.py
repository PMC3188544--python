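"""Exception hierarchy shared across the package."""


class TransheightError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TransheightError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class DegenerateInputError(TransheightError, ValueError):
    """Input admits no well-defined estimate (constant phenotype, n <= p, ...)."""


class UndefinedLDError(TransheightError, ValueError):
    """LD requested for a monomorphic variant."""


class NoPredictionError(TransheightError, ValueError):
    """Allele direction cannot be predicted because D == 0."""


class SchemaError(TransheightError, ValueError):
    """A file is missing required columns or is otherwise malformed."""


class MatchingError(TransheightError, RuntimeError):
    """Frequency-matched null sets could not be generated."""
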