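"""Exception hierarchy shared across the package."""


class MirrorCoevError(Exception):
    """Base class for all package errors."""


class FastaParseError(MirrorCoevError):
    """Input is not parseable FASTA (or is empty)."""


class RaggedAlignmentError(MirrorCoevError):
    """Sequences in one alignment have unequal lengths."""


class AlphabetError(MirrorCoevError):
    """A residue falls outside the accepted amino-acid alphabet."""


class InsufficientOverlapError(MirrorCoevError):
    """Two families share fewer species than the configured minimum."""


class UndefinedDistanceError(MirrorCoevError):
    """A sequence pair has no usable (both-canonical) sites."""


class MatrixFormatError(MirrorCoevError):
    """A distance-matrix file is non-square, asymmetric, or mislabelled."""


class UndefinedCorrelationError(MirrorCoevError):
    """Pearson correlation requested on a constant or too-short vector."""


class DomainError(MirrorCoevError):
    """An argument falls outside a statistical function's domain."""


class LookupFailure(MirrorCoevError):
    """A requested species or position is absent from the container."""


class ConfigError(MirrorCoevError):
    """A panel configuration is malformed."""
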