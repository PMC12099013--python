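"""Exception hierarchy for callidx."""


class CallidxError(Exception):
    """Base class for all callidx errors."""


class ValidationError(CallidxError, ValueError):
    """A parameter object violates one of its stated invariants."""


class SegmentationError(CallidxError):
    """Template alignment or mask propagation failed."""


class LandmarkError(CallidxError):
    """Landmark detection failed on a slice."""


class OpenBoundaryError(LandmarkError):
    """A boundary walk left the image before leaving the mask."""


class StatsError(CallidxError):
    """A statistical operation received unusable input."""
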