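"""Exception hierarchy shared by all pipeline stages."""


class IsletHullError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(IsletHullError):
    """Channel grids or masks do not share identical dimensions."""


class ConfigurationError(IsletHullError):
    """A channel map, config file or parameter set is invalid."""


class BoundsError(IsletHullError):
    """A crop, ROI or polygon extends beyond the image grid."""


class ValidationError(IsletHullError):
    """An input violates a stated precondition (duplicates, too small, ...)."""


class DegenerateGeometryError(IsletHullError):
    """A mask or polygon has no well-defined hull, area or perimeter."""


class IsletNotFoundError(IsletHullError):
    """Endocrine masks vanished during clean-up; the islet is skipped."""


class SimulationError(IsletHullError):
    """Synthetic-image parameters cannot be realised (infeasible packing)."""


class MetricsError(IsletHullError):
    """Metrics cannot be computed (e.g. empty islet-area mask)."""
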