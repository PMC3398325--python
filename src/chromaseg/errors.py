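"""Exception hierarchy shared across the package."""


class ChromasegError(Exception):
    """Base class for all package-specific errors."""


class ImageReadError(ChromasegError, OSError):
    """A raster file could not be read or decoded."""


class ImageWriteError(ChromasegError, OSError):
    """A raster file could not be written."""


class DegenerateBasisError(ChromasegError, ValueError):
    """The supplied stain vectors do not span a usable basis."""


class DegenerateHistogramError(ChromasegError, ValueError):
    """A histogram with a single occupied bin cannot be thresholded."""


class PlacementError(ChromasegError, RuntimeError):
    """A phantom object could not be placed without overlap."""
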