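"""Exception hierarchy.

Every failure mode of the pipeline maps to a named exception with a stable
``category`` string, so the command-line layer can emit machine-readable
error categories without string-matching messages.
"""


class CTMigrateError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(CTMigrateError):
    """A file exists but cannot be interpreted as a valid CT volume."""

    category = "format"


class AmbiguityError(CTMigrateError):
    """An input admits more than one interpretation (e.g. multi-series DICOM
    directory, or two detected beads too close to tell apart)."""

    category = "ambiguity"


class GenerationError(CTMigrateError):
    """Phantom generation failed: invalid geometry, bead collision, or the
    posed geometry leaves the voxel grid."""

    category = "generation"


class EmptyResultError(CTMigrateError):
    """A filtering operation produced nothing where at least one result is
    required (e.g. no connected component above the size floor)."""

    category = "empty-result"


class DegenerateGeometryError(CTMigrateError):
    """A point configuration does not determine a rigid transform
    (fewer than three pairs, or collinear points)."""

    category = "degenerate-geometry"


class InsufficientCorrespondenceError(CTMigrateError):
    """Bead matching yielded fewer than three correspondences."""

    category = "insufficient-correspondence"


class ConvergenceError(CTMigrateError):
    """The image registration optimizer exhausted its iteration budget.

    Carries the last iterate so callers can inspect how far it got.
    """

    category = "convergence"

    def __init__(self, message, last_transform=None, last_quality=None):
        super().__init__(message)
        self.last_transform = last_transform
        self.last_quality = last_quality


class InsufficientOverlapError(CTMigrateError):
    """Common-region masking kept less than the configured minimum fraction
    of the reference mask."""

    category = "insufficient-overlap"


class QualityError(CTMigrateError):
    """A registration verification came back red while running in strict
    mode."""

    category = "quality"


class InsufficientDataError(CTMigrateError):
    """A statistic needs more observations than were supplied."""

    category = "insufficient-data"


class DegenerateSampleError(CTMigrateError):
    """A sample has zero variance where spread is required (normality
    testing)."""

    category = "degenerate-sample"
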