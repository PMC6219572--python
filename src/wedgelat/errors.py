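"""Exception hierarchy for wedgelat."""


class WedgelatError(Exception):
    """Base class for all package errors."""


class ParameterError(WedgelatError, ValueError):
    """An input parameter violates its physical or structural constraints."""


class OverlapError(WedgelatError, ValueError):
    """Two wedges (or protein outlines) overlap sterically."""


class DegenerateParametersError(WedgelatError, ValueError):
    """The linear system for the deformation coefficients is singular."""


class BracketError(WedgelatError, ValueError):
    """A root bracket does not contain a sign change."""


class SolverError(WedgelatError, RuntimeError):
    """A numerical solve failed to converge."""


class GeometryError(WedgelatError, ValueError):
    """Invalid geometric configuration (e.g. overlapping footprints)."""


class DensityError(WedgelatError, RuntimeError):
    """A random configuration could not be placed at the requested density."""


class StateError(WedgelatError, RuntimeError):
    """An operation was requested on an object in an invalid state."""


class RangeError(WedgelatError, ValueError):
    """A quantity left its physically meaningful range."""
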