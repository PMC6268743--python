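"""Exception hierarchy.

All package-specific failures derive from :class:`SfeKineticsError` so callers
can catch one base class; the subclasses distinguish bad physical inputs from
algorithmic failures (segmentation, crossing search, solver stability).
"""


class SfeKineticsError(Exception):
    """Base class for all package errors."""


class DomainError(SfeKineticsError, ValueError):
    """A physical quantity is outside its admissible range."""


class CurveError(SfeKineticsError, ValueError):
    """An extraction curve violates its invariants (ordering, signs)."""


class ParseError(CurveError):
    """A curve or config file could not be parsed; carries file context."""


class SegmentationError(SfeKineticsError):
    """Too few points to split a curve into fast and slow periods."""


class NoCrossingError(SfeKineticsError):
    """The fitted fast- and slow-period segments do not cross."""


class InconsistencyError(SfeKineticsError):
    """Derived quantities violate a model identity (e.g. r outside (0, 1])."""


class InfeasibilityError(SfeKineticsError):
    """Parameter combination is physically impossible (e.g. the in-bed
    solvent could not have reached the saturation concentration)."""


class ConvergenceError(SfeKineticsError):
    """A least-squares fit failed to converge from every start point."""


class StepSizeError(SfeKineticsError):
    """Explicit time step violates the stability (CFL) constraint."""


class InstabilityError(SfeKineticsError):
    """The plug-flow solver produced unphysical negative concentrations."""


class SchemaError(SfeKineticsError, ValueError):
    """A report or manifest is missing required fields."""
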