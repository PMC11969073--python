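"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`PartialOarError` so callers can catch
a single base class at pipeline boundaries.
"""


class PartialOarError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PartialOarError):
    """A DICOM object is not of the expected kind or is missing required data."""


class GeometryError(PartialOarError):
    """Masks or grids are geometrically incompatible (e.g. different lattices)."""


class EmptyStructureError(PartialOarError):
    """An operation that requires a non-empty structure received an empty one."""


class UndefinedScoreError(PartialOarError):
    """An agreement score is undefined (e.g. both masks empty)."""


class NormalizationError(PartialOarError):
    """Prescription normalization is impossible (zero coverage dose)."""


class AlignmentError(PartialOarError):
    """Two cohort tables cannot be aligned subject-by-subject."""


class PhantomSpecError(PartialOarError):
    """A phantom specification is internally inconsistent or exceeds its grid."""
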