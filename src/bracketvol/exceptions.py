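"""Exception and warning types raised across the pipeline."""


class BracketVolError(Exception):
    """Base class for all package errors."""


class UnreadableImage(BracketVolError):
    """The input file could not be decoded as a raster image."""


class EmptySilhouette(BracketVolError):
    """No foreground pixel survived binarization."""


class DegenerateSilhouette(BracketVolError):
    """The foreground component is smaller than 2 px in some dimension."""


class TooFewPoints(BracketVolError):
    """An outline has too few points to support the local-regression window."""


class ViewLengthMismatch(BracketVolError):
    """Lateral and ventral views disagree on the body-axis pixel span."""


class InvalidExponent(BracketVolError):
    """Superelliptical exponent must be strictly positive."""


class OutOfChord(BracketVolError):
    """Chordwise position outside the [0, 1] chord fraction range."""


class EmptyProfile(BracketVolError):
    """Axial profile has no usable stations."""


class NonPositiveDiameter(BracketVolError):
    """An interior station carries a zero or negative diameter."""


class DegeneratePlanform(BracketVolError):
    """A fin planform with no positive chord anywhere along the span."""


class NotCloseable(BracketVolError):
    """Mesh cleaning left boundary (hole) edges; typically a low-resolution
    or unsmoothed-input failure."""


class NotWatertight(BracketVolError):
    """Volume requested on a mesh that has not been cleaned watertight."""


class BadDimension(BracketVolError):
    """Unit conversion dimension must be 2 (area) or 3 (volume)."""


class UnsupportedFormat(BracketVolError):
    """Mesh export format not among PLY / OBJ / STL."""


class ConfigError(BracketVolError):
    """Invalid run configuration."""


class LowResolutionWarning(UserWarning):
    """Silhouette long axis below the recommended 3,000 px."""
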