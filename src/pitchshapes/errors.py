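"""Exception types shared across the pipeline."""


class PitchShapesError(Exception):
    """Base class for pipeline errors."""


class DegenerateShapeError(PitchShapesError, ValueError):
    """A point set or polygon has no usable area (collinear points,
    sub-pixel raster, fewer than three players after goalkeeper removal)."""


class DataError(PitchShapesError, ValueError):
    """Input files or tables are missing, empty, or inconsistent."""
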