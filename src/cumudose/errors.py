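"""Exception hierarchy shared across the pipeline stages."""


class CumudoseError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CumudoseError):
    """Invalid lattice geometry (non-positive spacing, bad shape)."""


class FrameError(CumudoseError):
    """Operation mixing grids that live on different coordinate frames."""


class UnitError(CumudoseError):
    """Dose-unit misuse, e.g. accumulating physical Gy or double EQD2 conversion."""


class DomainError(CumudoseError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateLandmarksError(CumudoseError):
    """Too few or collinear landmark pairs for a rigid fit."""


class EmptyStructureError(CumudoseError):
    """A DVH or overlap query on a structure with no occupied voxels."""


class ConfigurationError(CumudoseError):
    """Invalid or incomplete course / pipeline configuration."""


class PhantomSpecError(CumudoseError):
    """Synthetic-phantom specification violating a generator guard."""
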