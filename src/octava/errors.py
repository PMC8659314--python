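"""Exception hierarchy shared across the toolbox."""


class OctavaError(Exception):
    """Base class for all toolbox errors."""


class FormatError(OctavaError):
    """Input file is not a supported grayscale raster."""


class GeometryError(OctavaError):
    """A region of interest or phantom geometry does not fit the image."""


class ParameterError(OctavaError):
    """A parameter is outside its valid range."""


class DegenerateImageError(OctavaError):
    """The image has no usable contrast (e.g. constant intensity)."""


class UndefinedMetricError(OctavaError):
    """A metric is undefined for this input (e.g. empty network)."""
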