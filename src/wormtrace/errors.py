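"""Exception hierarchy used across the toolkit."""


class WormtraceError(Exception):
    """Base class for all toolkit errors."""


class FormatError(WormtraceError):
    """A recording, spline, stage, or time file is malformed."""


class SegmentationError(WormtraceError):
    """A frame could not be segmented into a usable worm mask/outline."""


class UnusableMaskError(SegmentationError):
    """Binary mask is all-foreground, all-background, or empty after debris removal."""


class AmbiguousHeadError(SegmentationError):
    """Head and tail candidates cannot be told apart."""


class MidlineFitError(SegmentationError):
    """Midline construction failed (e.g., self-intersecting midline from an omega posture)."""


class AnalysisError(WormtraceError):
    """Inputs violate a precondition of an analysis operation."""


class NoInflectionError(AnalysisError):
    """dV/dt never reaches the inflection criterion before the AP peak.

    Callers should fall back to the fixed-lead threshold method.
    """
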