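"""Exception hierarchy shared across the package."""


class TopoIndexError(Exception):
    """Base class for all package-specific errors."""


class StackIOError(TopoIndexError):
    """Raised for unreadable files, bad channel maps, or inconsistent pages."""


class EmptyMaskError(TopoIndexError):
    """Raised when an operation requires a nonempty mask and gets none."""


class SegmentationError(TopoIndexError):
    """Raised when thresholding cannot produce a usable mask."""


class DegenerateBoundaryError(TopoIndexError):
    """Raised when dorsal and ventral extents coincide (TI undefined)."""


class QuantError(TopoIndexError):
    """Raised for undefined ratio normalizations (zero reference signal)."""


class StatsError(TopoIndexError):
    """Raised for invalid statistical inputs (single group, zero variance...)."""


class PipelineStageError(TopoIndexError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
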