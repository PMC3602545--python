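"""Exception hierarchy shared across the pipeline stages."""


class SlfcError(Exception):
    """Base class for all package-specific errors."""


class SizingError(SlfcError):
    """A grid is too small to host the requested structure."""


class SpecificationError(SlfcError):
    """A cohort / epoch / table specification is internally inconsistent."""


class ConflictError(SpecificationError):
    """Two planted facts contradict each other (e.g. duplicate edge, two strengths)."""


class DegenerateImageError(SlfcError):
    """An image has no intensity structure to register against."""


class ConvergenceError(SlfcError):
    """Iterative spatial normalization failed to converge; carries the final objective."""

    def __init__(self, message: str, objective: float | None = None):
        super().__init__(message)
        self.objective = objective


class WindowError(SlfcError):
    """An analysis window falls outside the recorded signal."""


class ParseError(SlfcError):
    """A delimited table could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyIntersectionError(SlfcError):
    """A seed ROI definition produced no voxels."""
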