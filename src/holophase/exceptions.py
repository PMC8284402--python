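"""Exception hierarchy.

All library errors derive from :class:`HolophaseError` so callers (and the
CLI) can distinguish usage problems from data problems.
"""


class HolophaseError(Exception):
    """Base class for all holophase errors."""


class GeometryError(HolophaseError, ValueError):
    """Invalid acquisition geometry (non-positive or inverted distances...)."""


class SamplingError(HolophaseError, ValueError):
    """Unsupported sampling: non-square pixels, mismatched grids."""


class DegenerateDistanceError(HolophaseError, ValueError):
    """An operation that needs propagation got an (effective) distance of 0."""


class DataError(HolophaseError, ValueError):
    """Invalid or inconsistent image data (negative intensities, bad flats...)."""


class CorrectionError(DataError):
    """Flat/dark correction is ill-defined (flat - dark <= 0 somewhere)."""


class AlignmentError(DataError):
    """Image registration failed (e.g. all-zero image, undefined correlation)."""


class DivergenceError(HolophaseError, RuntimeError):
    """An iterative scheme produced a non-finite objective value."""
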