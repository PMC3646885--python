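"""Exception hierarchy for mhcscan.

Every malformed-input condition named in the I/O and statistics layers maps
to a distinct exception class so callers (and the CLI) can report the failing
stage precisely.
"""


class MhcscanError(Exception):
    """Base class for all package errors."""


class AlignmentError(MhcscanError):
    """Base class for codon-alignment validation failures."""


class FrameViolationError(AlignmentError):
    """Alignment length is not divisible by 3."""


class UnequalLengthError(AlignmentError):
    """Sequences in the alignment differ in length."""


class DuplicateIdError(AlignmentError):
    """Two records share the same allele id."""


class EmptyAlignmentError(AlignmentError):
    """No records found."""


class InvalidCharacterError(AlignmentError):
    """A sequence contains characters outside A, C, G, T, N, -."""


class InvalidRegionError(MhcscanError):
    """Region coordinates fall outside the alignment."""


class BoundaryError(MhcscanError):
    """Default domain boundary cannot apply to a short alignment."""


class GenotypeTableError(MhcscanError):
    """Genotype table violates its invariants (unknown allele, >2 alleles...)."""


class FrequencyTableError(MhcscanError):
    """Frequency table violates its invariants (negative counts...)."""


class InvalidCodonError(MhcscanError):
    """Codon contains gaps/ambiguity or is a stop codon where one is not allowed."""


class InsufficientDataError(MhcscanError):
    """Operation requires more sequences/samples/sites than supplied."""


class DegenerateLDError(MhcscanError):
    """LD permutation test inputs have no variance in LD values or distances."""


class SimulationError(MhcscanError):
    """Synthetic-data generator could not satisfy its constraints."""


class ComparisonError(MhcscanError):
    """Two population results cannot be compared (mismatched codon sets...)."""
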