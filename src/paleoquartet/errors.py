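"""Named exceptions used across the package."""


class PaleoquartetError(ValueError):
    """Base class for all package-specific errors."""


class AlignmentError(PaleoquartetError):
    """Malformed alignment or sequence set."""


class DuplicateHeaderError(AlignmentError):
    """Two FASTA records share the same header."""


class EmptyRecordError(AlignmentError):
    """A FASTA record has an empty sequence."""


class MixedAlphabetError(AlignmentError):
    """DNA and amino-acid sequences mixed in one set."""


class InternalStopError(AlignmentError):
    """A stop codon occurs before the end of the coding sequence."""


class PartitionError(AlignmentError):
    """Partition map is not disjoint, contiguous and covering."""


class SimulationError(PaleoquartetError):
    """Invalid simulation specification or seed."""


class TreeError(PaleoquartetError):
    """Invalid tree, taxon mismatch or degenerate quartet input."""


class IntervalError(PaleoquartetError):
    """Malformed genomic interval."""
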