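"""Exception hierarchy shared by all pipeline stages."""


class CoeruleusError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedGeometryError(CoeruleusError):
    """Raised for oblique/rotated affines or otherwise unsupported grids."""


class GridCompatibilityError(CoeruleusError):
    """Raised when a voxelwise operation receives volumes on different grids."""


class SliceRangeError(CoeruleusError, IndexError):
    """Raised when a slice index or z coordinate falls outside the grid."""


class EmptyMaskError(CoeruleusError):
    """Raised when an operation requires a nonempty mask and got none."""


class DegenerateRegionError(CoeruleusError):
    """Raised when a region is too uniform to estimate noise (SD == 0)."""


class UndefinedDiceError(CoeruleusError):
    """Raised when Dice overlap is requested for two empty masks."""


class GenerationError(CoeruleusError):
    """Raised when a phantom subject cannot be generated (e.g. tube off-grid)."""


class ConfigurationError(CoeruleusError):
    """Raised for invalid or inconsistent analysis configuration."""


class StageError(CoeruleusError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
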