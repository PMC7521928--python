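"""Exception types shared across the package."""


class EnspatialError(Exception):
    """Base class for all package-specific errors."""


class CenterOutsideFrameError(EnspatialError, ValueError):
    """A circle center falls outside the rectangular image frame."""


class NoCentersError(EnspatialError, ValueError):
    """No cell of the requested center phenotype exists in any frame."""


class DegenerateSampleError(EnspatialError, ValueError):
    """A gamma fit was requested on a degenerate sample (zero mean or variance)."""


class GridMismatchError(EnspatialError, ValueError):
    """Observed profile and null distribution disagree on radii or phenotypes."""


class ConfigurationError(EnspatialError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class SchemaError(EnspatialError, ValueError):
    """A cell table is missing required columns."""


class CellTableError(EnspatialError, ValueError):
    """A cell table row failed validation (bad phenotype or coordinate)."""
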