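"""Exception and warning types shared across the package."""


class PhenobankError(Exception):
    """Base class for all package-specific errors."""


class UnusableCardError(PhenobankError, ValueError):
    """Color-card patch too dark/degenerate to derive white-balance gains."""


class NoForegroundError(PhenobankError, ValueError):
    """Segmentation found no foreground object."""


class DegenerateOutlineError(PhenobankError, ValueError):
    """An outline has too few distinct points, zero area or self-intersects."""


class DegenerateTemplateError(PhenobankError, RuntimeError):
    """A shape template kept producing self-intersecting outlines."""


class GridMismatchError(PhenobankError, ValueError):
    """Two color histograms were built on different bin grids."""


class BorderClipWarning(UserWarning):
    """Foreground touches the image border; the outline may be clipped."""
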