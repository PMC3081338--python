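"""Exception hierarchy for the bcdburst pipeline."""


class BcdBurstError(Exception):
    """Base class for all package errors."""


class GenerationError(BcdBurstError):
    """Synthetic embryo could not be rendered (e.g. nuclei cannot be placed)."""


class SegmentationError(BcdBurstError):
    """Nucleus segmentation or axis estimation failed."""


class PlateauNotFoundError(BcdBurstError):
    """Threshold scan showed no stable plateau.

    Carries the full scan table so the failure can be inspected.
    """

    def __init__(self, message, scan_table=None):
        super().__init__(message)
        self.scan_table = scan_table


class HillFitError(BcdBurstError):
    """Hill-response fit failed to converge or data had the wrong orientation."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class PipelineError(BcdBurstError):
    """A pipeline stage failed; message names the stage and context."""
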