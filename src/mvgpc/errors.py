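"""Exception hierarchy shared across the package."""


class MvgpcError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MvgpcError, ValueError):
    """A parameter is outside its documented domain."""


class ShapeError(MvgpcError, ValueError):
    """Array shapes or grids do not match."""


class MissingDataError(MvgpcError, KeyError):
    """A required condition, subject, or group is absent."""


class AlignmentError(MvgpcError, ValueError):
    """Row metadata of two tables does not line up."""


class RankError(MvgpcError, ValueError):
    """A design matrix is rank deficient."""


class InvalidLabelError(MvgpcError, ValueError):
    """Class labels are not a valid two-class +/-1 coding."""


class ConvergenceError(MvgpcError, RuntimeError):
    """An iterative solver failed to converge."""

    def __init__(self, message: str, n_iterations: int | None = None):
        super().__init__(message)
        self.n_iterations = n_iterations


class UnsupportedKernelError(MvgpcError, ValueError):
    """Operation requires a linear kernel."""


class PairingError(MvgpcError, ValueError):
    """Group pairing for leave-one-pair-out is invalid."""


class PipelineStageError(MvgpcError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
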