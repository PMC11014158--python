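"""Exception types shared across the package."""


class LSFMError(Exception):
    """Base class for package errors."""


class FormatError(LSFMError, ValueError):
    """Input file is not a readable grayscale TIFF of a supported depth."""


class ShapeError(LSFMError, ValueError):
    """Array shapes are inconsistent (slices, patch grids, metric pairs)."""


class RangeError(LSFMError, ValueError):
    """Intensities outside the normalised [0, 1] contract."""


class SizeError(LSFMError, ValueError):
    """A patch, window or sequence does not fit the data extent."""


class GridError(LSFMError, ValueError):
    """Patch list does not match its grid metadata."""


class DataError(LSFMError, ValueError):
    """Empty or invalid data passed to a corpus/training operation."""


class ParameterError(LSFMError, ValueError):
    """Invalid configuration value."""


class PackingError(LSFMError, RuntimeError):
    """Bead placement could not satisfy the separation constraint."""


class TruncationError(LSFMError, ValueError):
    """An intensity profile never falls to half maximum inside the stack."""


class CoordinateError(LSFMError, ValueError):
    """A detection or center lies outside the volume."""
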