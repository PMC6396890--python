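"""Exception hierarchy shared by the pipeline stages."""


class SplicevoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SplicevoError):
    """Malformed input file (empty FASTA, ragged alignment, bad GFF3...)."""


class AlphabetError(FormatError):
    """Illegal character for the declared sequence alphabet."""


class RangeError(SplicevoError):
    """Coordinates fall outside the sequence they refer to."""


class MappingError(SplicevoError):
    """Spliced CDS-to-genomic mapping failed to cover enough of the CDS."""


class DegenerateIntronError(SplicevoError):
    """Intron too short to carry donor and acceptor dinucleotides."""


class NotationError(SplicevoError):
    """Inconsistent or unparseable junction notation."""


class PatternSyntaxError(SplicevoError):
    """Malformed PROSITE pattern."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


class AlignmentError(SplicevoError):
    """Rows of unequal length or otherwise unusable alignment."""


class UndefinedDistanceError(SplicevoError):
    """No comparable columns between two rows."""


class SaturationError(SplicevoError):
    """A distance is saturated (infinite) where a finite one is required."""


class LabelError(SplicevoError):
    """Duplicate or illegal taxon/leaf labels."""


class ConfigError(SplicevoError):
    """Invalid simulation or pipeline configuration."""
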