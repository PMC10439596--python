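"""Exception hierarchy for femrot."""


class FemrotError(Exception):
    """Base class for all femrot errors."""


class InvalidSpecError(FemrotError):
    """A femur specification violates its invariants (e.g. zero condylar width)."""


class EmptyCohortError(FemrotError):
    """A cohort of size zero was requested."""


class DegenerateFitError(FemrotError):
    """Circle fit on collinear or otherwise degenerate points."""


class DegenerateAxisError(FemrotError):
    """An axis is defined by coincident points; carries the axis name."""


class DegenerateProjectionError(FemrotError):
    """A direction is (numerically) parallel to the plane normal."""


class UnbalancedTableError(FemrotError):
    """A measurement table is missing repeats required for ICC."""
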