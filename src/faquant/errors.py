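"""Exception types shared across the package."""


class FaquantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FaquantError, ValueError):
    """Invalid argument or precondition violation."""


class NoContrastError(FaquantError):
    """Raised when an operation requiring intensity contrast receives a
    constant image (e.g. Otsu thresholding)."""


class DegenerateProfileError(FaquantError):
    """Raised when a line profile channel is constant and cannot be
    min-max normalized."""


class PlacementError(FaquantError):
    """Raised when the synthetic generator cannot place the requested
    objects without overlap within the retry budget."""


class UnassignedRegionError(FaquantError):
    """Raised when an object's centroid falls outside the cell mask and
    cannot be assigned to the inner or outer compartment."""
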