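"""Exception hierarchy.

Validation problems (bad inputs, schemas, conventions) and computation
problems (degenerate geometry, non-convergence, no detectable cycles) are
kept on separate branches so callers — the CLI in particular — can map
them to distinct exit codes.
"""


class GaitError(Exception):
    """Base class for all errors raised by gaitmark."""


class ValidationError(GaitError, ValueError):
    """An input value violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A file or table does not match the declared dialect/schema."""


class OrderingError(SchemaError):
    """Frame indices are not strictly increasing."""


class AlignmentError(ValidationError):
    """Two summary collections do not share subjects/parameters."""


class ComputationError(GaitError):
    """A well-formed input defeats the computation."""


class DegenerateGeometryError(ComputationError):
    """A zero-length segment makes a joint angle undefined."""


class GapError(ComputationError):
    """A low-visibility run is too long to interpolate across."""


class NoCyclesError(ComputationError):
    """Fewer than two qualifying peaks: no gait cycle can be delimited."""


class ConvergenceError(ComputationError):
    """Iterative undistortion failed to converge."""


class DegenerateStatisticError(ComputationError):
    """A statistic is undefined for this sample (e.g. zero variance)."""


class UndefinedCorrelationError(DegenerateStatisticError):
    """Rank correlation undefined: a system has zero rank variance."""
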