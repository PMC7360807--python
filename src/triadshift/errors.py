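"""Exception hierarchy for the triadshift pipeline.

Every error raised on purpose by this package derives from
:class:`TriadshiftError`, so callers can catch pipeline problems without
masking programming errors.
"""


class TriadshiftError(Exception):
    """Base class for all triadshift errors."""


class MalformedTableError(TriadshiftError):
    """A tabular input file violates its format contract (missing header,
    ragged rows, duplicated gene rows, non-numeric or negative values)."""


class DesignMismatchError(TriadshiftError):
    """Samples and the design table disagree, or a requested condition is
    absent from the design."""


class DuplicateTriadIdError(TriadshiftError):
    """The same triad identifier occurs more than once in a triad map."""


class DuplicateGeneAcrossTriadsError(TriadshiftError):
    """A gene identifier is claimed by more than one triad, or twice within
    one triad."""


class MissingGeneError(TriadshiftError):
    """A triad member gene is absent from the expression matrix."""


class MissingTriadError(TriadshiftError):
    """A pyrosequencing-assayed triad has no RNA-seq classification."""


class NotOnSimplexError(TriadshiftError):
    """A relative-abundance triple is not on the unit simplex."""


class InvalidCountsError(TriadshiftError):
    """Hypergeometric counts violate 0 <= k <= min(n, K) and n, K <= N."""


class QueryOutsidePopulationError(TriadshiftError):
    """An enrichment query contains genes outside the background population
    (strict mode)."""


class InfeasibleConfigError(TriadshiftError):
    """A generator configuration cannot be satisfied (e.g. more activated
    genes requested than genes available)."""


class EmptyIntersectionError(TriadshiftError):
    """Two classifications to be traced share no triads."""


class ValueOutOfRangeError(TriadshiftError):
    """A numeric argument is outside its valid range (e.g. a p-value
    outside [0, 1])."""


class PipelineDependencyError(TriadshiftError):
    """A pipeline stage was requested but a stage it depends on is disabled
    or has not produced its output."""


class StageError(TriadshiftError):
    """Wraps an error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")
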