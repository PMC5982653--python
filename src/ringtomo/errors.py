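"""Exception hierarchy for ringtomo."""


class RingTomoError(Exception):
    """Base class for all ringtomo errors."""


class GeometryError(RingTomoError, ValueError):
    """Invalid acquisition geometry or an interval that does not tile the scan span."""


class PrecisionError(GeometryError):
    """Requested angle interval finer than the rotary-table precision."""


class ConfigurationError(RingTomoError, ValueError):
    """Invalid processing or acquisition configuration (bad band, too few samples, ...)."""


class MeasurementError(RingTomoError, ValueError):
    """Inconsistent measurement inputs (e.g. opposing distances overlapping)."""


class StackingError(RingTomoError, ValueError):
    """Slices cannot be stacked into a volume (shape / metadata mismatch)."""
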