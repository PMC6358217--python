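"""Exception hierarchy for the oopolar pipeline.

Every failure mode raised by the library derives from :class:`OopolarError`
so batch drivers can catch one type and keep their output tables rectangular.
"""


class OopolarError(Exception):
    """Base class for all oopolar errors."""


class InvalidInputError(OopolarError, ValueError):
    """Input violates a precondition (out-of-bounds anchor, empty sample...)."""


class SnapFailureError(OopolarError):
    """No membrane-like pixel found near an anchor during snapping."""

    def __init__(self, anchor_label: str, message: str | None = None):
        self.anchor_label = anchor_label
        super().__init__(message or f"anchor {anchor_label!r}: no pixel above "
                         "background within the snap radius")


class TracingError(OopolarError):
    """The membrane contour could not be traced or closed.

    ``diagnostic_mask`` (when set) holds the binary mask that tracing
    worked on, for visual debugging.
    """

    def __init__(self, message: str, diagnostic_mask=None):
        self.diagnostic_mask = diagnostic_mask
        super().__init__(message)


class InvalidAnchorError(OopolarError):
    """Anchor placement incompatible with the requested partition."""


class ConfigurationError(OopolarError):
    """Partition or pipeline configuration is geometrically impossible."""


class DegenerateGeometryError(OopolarError):
    """A region became empty after erosion/clipping."""


class UndefinedCorrelationError(OopolarError):
    """Pearson correlation undefined (zero variance within the mask)."""


class InsufficientOverlapError(OopolarError):
    """Mask and rotated mask overlap on too few pixels for the rotation null."""


class ThresholdError(OopolarError):
    """Automatic thresholding impossible (constant channel)."""


class PlacementError(OopolarError):
    """Puncta could not be placed under the disjointness constraint."""


class BleachDetectionError(OopolarError):
    """No bleach event could be located in a FRAP series."""


class SpecError(OopolarError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
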