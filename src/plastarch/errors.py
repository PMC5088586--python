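"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`PlastarchError`
so the CLI can map validation problems to a distinct exit code.
"""


class PlastarchError(Exception):
    """Base class for all package errors."""


class FormatError(PlastarchError):
    """Malformed input file (FASTA/feature table/registry)."""


class CoordinateError(PlastarchError):
    """Feature interval outside the declared sequence bounds."""


class ValidationError(PlastarchError):
    """Inconsistent in-memory data (non-permutation, ragged alignment, ...)."""


class UndefinedStatisticError(PlastarchError):
    """A statistic has no defined value on this input (e.g. all-N sequence)."""


class SaturationError(PlastarchError):
    """Observed divergence outside the domain of the distance formula."""


class InsufficientDataError(PlastarchError):
    """Too few shared genes / family members to run the analysis."""


class DuplicationError(PlastarchError):
    """A gene occurs more than once outside the inverted repeat."""


class HomologyError(PlastarchError):
    """Host/reference alignment identity too low to trust the mapping."""


class AnnotationError(PlastarchError):
    """Motif/window annotations are mutually inconsistent."""


class ConfigError(PlastarchError):
    """Simulation or pipeline configuration is infeasible."""


class StageError(PlastarchError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
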