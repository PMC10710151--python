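"""Exception hierarchy shared across the package."""


class GpcrVarError(Exception):
    """Base class for all package errors."""


class FormatError(GpcrVarError):
    """A coordinate file could not be parsed in the requested format."""


class StructuralInconsistencyError(GpcrVarError):
    """Models of a multi-model file disagree in atom count or identity."""


class EmptySelectionError(GpcrVarError):
    """A segment definition resolved to zero atoms."""


class ParameterError(GpcrVarError):
    """An operation received an out-of-range parameter."""


class DegenerateGeometryError(GpcrVarError):
    """Coincident centres of mass or parallel vectors made a plane undefined."""


class PairingError(GpcrVarError):
    """Two distance series that must describe the same segment pair do not."""


class EvidenceError(GpcrVarError):
    """Classification was requested without the mandatory TM6 evidence."""


class ConstraintError(GpcrVarError):
    """Synthetic-data targets are geometrically or logically unsatisfiable."""


class LookupError_(GpcrVarError):
    """A requested residue is absent from the frame."""
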