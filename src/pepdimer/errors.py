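"""Exception hierarchy."""


class PepdimerError(Exception):
    """Base class for all package errors."""


class TrajectoryParseError(PepdimerError):
    """A structure file could not be parsed."""


class TrajectoryFormatError(PepdimerError):
    """A trajectory cannot be represented in the requested file format."""


class StructuralError(PepdimerError):
    """Inconsistent topology (e.g. differing atom counts across models)."""


class SelectionError(PepdimerError):
    """An atom selection could not be resolved."""


class DegenerateGeometryError(PepdimerError):
    """Geometry is degenerate (collinear points, zero-length vectors...)."""


class ConstructionError(PepdimerError):
    """A synthetic template's constraints are unrealizable."""


class WHAMError(PepdimerError):
    """Umbrella-sampling data cannot be combined into a PMF."""


class ConfigurationError(PepdimerError):
    """Invalid configuration or lookup-table miss."""
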