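"""Exception hierarchy for mitocompare.

Every stage raises a subclass of :class:`MitocompareError`, so callers (and the
CLI) can catch one base type and still discriminate by stage.
"""


class MitocompareError(Exception):
    """Base class for all package errors."""


class ParseError(MitocompareError):
    """A file could not be parsed (missing sequence, empty file, bad header)."""


class CoordinateError(MitocompareError):
    """Feature coordinates are inconsistent (end < start, beyond genome end)."""


class DuplicateFeatureError(MitocompareError):
    """Two features with identical names overlap in one table."""


class EmptyTableError(MitocompareError):
    """A feature table contains a header but no rows."""


class OrderingError(MitocompareError):
    """A feature table is not in genomic order where order is required."""


class AlphabetError(MitocompareError):
    """A sequence contains characters outside A/C/G/T/N."""


class EmptyInputError(MitocompareError):
    """An operation received an empty sequence."""


class DegenerateInputError(MitocompareError):
    """A sequence contains no countable (non-N) bases."""


class IncompleteAnnotationError(MitocompareError):
    """A required region or annotation field is missing from the table."""


class FrameError(MitocompareError):
    """A coding sequence length is incompatible with codon structure."""


class TooShortError(MitocompareError):
    """A sequence is below the minimum length for the operation."""


class DomainError(MitocompareError):
    """An argument is outside the mathematical domain of the operation."""


class FoldError(MitocompareError):
    """Base class for tRNA folding failures."""


class AnchorError(FoldError):
    """The anticodon triplet does not occur in the tRNA sequence."""


class FoldFailureError(FoldError):
    """No template-consistent cloverleaf decomposition exists."""


class StructureError(MitocompareError):
    """A secondary-structure object is internally inconsistent."""


class SaturationError(MitocompareError):
    """Substitution proportion too high for the distance correction."""


class InsufficientDataError(MitocompareError):
    """Fewer taxa/observations than the operation requires."""


class MissingDataError(MitocompareError):
    """A taxon lacks a gene required for the supermatrix."""


class AlignmentRequiredError(MitocompareError):
    """Per-gene blocks have unequal lengths and no alignment was supplied."""


class UndefinedDistanceError(MitocompareError):
    """No comparable columns between two sequences."""


class InputError(MitocompareError):
    """Invalid matrix or tree input."""


class NameError_(MitocompareError):
    """An unknown taxon, gene, or fixture name was requested."""


class GenerationError(MitocompareError):
    """The synthetic-data generator received an infeasible configuration."""


class ConfigError(MitocompareError):
    """Invalid simulation or run configuration."""


class PipelineStageError(MitocompareError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
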