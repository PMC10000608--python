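"""Exception hierarchy for ovometry.

All package-specific failures derive from :class:`OvometryError` so callers can
catch one base class; the leaves distinguish degenerate geometry from bad data.
"""


class OvometryError(Exception):
    """Base class for all ovometry errors."""


class DegenerateInputError(OvometryError, ValueError):
    """Inputs coincide or are otherwise too degenerate to define the result."""


class GeometryError(OvometryError, ValueError):
    """A geometric construction is undefined for this configuration."""


class CollinearityError(GeometryError):
    """Points required to be collinear are not, beyond tolerance."""


class IdealPointError(GeometryError):
    """A finite point was required but an ideal point (at infinity) was given."""


class InconsistentConfigurationError(GeometryError):
    """Image measurements are inconsistent with any physical plane layout."""


class InsufficientDataError(OvometryError, ValueError):
    """Not enough segments/pixels/samples to estimate the quantity."""


class ParameterError(OvometryError, ValueError):
    """A scalar parameter is outside its admissible range."""


class PaletteError(OvometryError, ValueError):
    """A raster color does not match any label-palette entry."""


class EmptySegmentationError(OvometryError, ValueError):
    """A required class region contains no pixels."""


class TagError(OvometryError, ValueError):
    """Axis endpoint sets with inconsistent tags were combined."""


class ShapeError(OvometryError, ValueError):
    """Array/list dimensions do not agree."""


class BehindCameraError(GeometryError):
    """A world point lies at or behind the camera center."""


class FramingError(OvometryError, ValueError):
    """The rendered object falls entirely outside the image frame."""


class FixtureCorruptionError(OvometryError, RuntimeError):
    """A bundled data table does not match its recorded checksum."""


class DegenerateRegressionError(OvometryError, ValueError):
    """Regression is undefined (constant predictor or too few samples)."""
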