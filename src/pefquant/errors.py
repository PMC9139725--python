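"""Exception types shared across the package."""


class PefquantError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(PefquantError, ValueError):
    """An image does not have the expected number of dimensions."""


class GridMismatchError(PefquantError, ValueError):
    """Two images do not share the same voxel grid (shape and spacing)."""


class GenerationError(PefquantError, RuntimeError):
    """A phantom could not be generated under the requested geometry."""
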