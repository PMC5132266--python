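"""Exception hierarchy shared by all analysis stages."""


class CholmapError(Exception):
    """Base class for all package errors."""


class FormatError(CholmapError):
    """A structure or trajectory file could not be parsed."""


class TopologyMismatchError(CholmapError):
    """Trajectory bead count does not match the topology."""


class EmptyTrajectoryError(CholmapError):
    """No frames remain after discarding the equilibration segment."""


class TriclinicBoxError(CholmapError):
    """Only orthorhombic simulation boxes are supported."""


class IllConditionedFitError(CholmapError):
    """The superposition selection is too small or degenerate."""


class PackingError(CholmapError):
    """Requested lipid count exceeds the available membrane area."""


class GeometryMismatchError(CholmapError):
    """Density grids have incompatible origin, spacing or shape."""
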