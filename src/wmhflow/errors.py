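"""Exception hierarchy shared across the pipeline stages."""


class WmhflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(WmhflowError, ValueError):
    """A numeric parameter violates its documented domain."""


class GeometryError(WmhflowError, ValueError):
    """Continuous or voxel geometry is inconsistent (overlap, out of field of view)."""


class GridMismatchError(WmhflowError, ValueError):
    """Two volumes that must share a grid differ in shape, spacing or origin."""


class SeedSnapError(WmhflowError, ValueError):
    """An inflow seed point could not be matched to a skeleton endpoint."""


class TopologyError(WmhflowError, ValueError):
    """The vascular network is not solvable (disconnected component, no inflow)."""


class ModelError(WmhflowError, ValueError):
    """A statistical model cannot be fitted (rank deficiency, empty groups)."""


class EmptyInputError(WmhflowError, ValueError):
    """An operation received an empty mask or an empty collection."""
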