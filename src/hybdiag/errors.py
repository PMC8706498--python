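"""Exception hierarchy with stable exit codes for the CLI."""


class HybdiagError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class AlignmentShapeError(HybdiagError):
    """Sequences in one alignment do not share a common length."""

    exit_code = 3


class AlphabetError(HybdiagError):
    """A residue outside the IUPAC nucleotide alphabet was encountered."""

    exit_code = 4


class MetadataError(HybdiagError):
    """Malformed or inconsistent sample metadata."""

    exit_code = 5


class ConcatenationError(HybdiagError):
    """Loci cannot be concatenated (sample sets differ)."""

    exit_code = 6


class ConfigurationError(HybdiagError):
    """Invalid analysis configuration (empty group, missing sites, ...)."""

    exit_code = 7


class UndefinedDistanceError(HybdiagError):
    """A pairwise distance has no comparable sites."""

    exit_code = 8


class ParameterError(HybdiagError):
    """Infeasible simulation parameters."""

    exit_code = 9


class ScoringError(HybdiagError):
    """Outputs and simulation truth do not refer to the same samples."""

    exit_code = 10
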