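"""Exception hierarchy for cycleprof."""


class CycleprofError(Exception):
    """Base class for all cycleprof errors."""


class ValidationError(CycleprofError, ValueError):
    """Inconsistent parameters or out-of-range arguments."""


class SegmentationError(CycleprofError):
    """A mask could not be produced (empty foreground, emptied by erosion...)."""


class DegenerateShapeError(CycleprofError):
    """Mask shape incompatible with a medial-line representation."""


class FitError(CycleprofError):
    """A model fit could not be performed (e.g. all lengths identical)."""


class EmptyProfileError(CycleprofError):
    """No length bin satisfied the minimum-count requirement."""


class SchemaError(CycleprofError):
    """A record file has a missing/unknown schema header or column."""
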