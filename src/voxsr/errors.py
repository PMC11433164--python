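"""Exception hierarchy shared across the toolkit."""


class VoxsrError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(VoxsrError, ValueError):
    """An argument is outside its documented domain."""


class ShapeError(VoxsrError, ValueError):
    """Array dimensions are inconsistent with the operation's contract."""


class FormatError(VoxsrError, ValueError):
    """A file exists but does not encode a supported volume."""


class VolumeTooSmallError(ParameterError):
    """Degradation would produce a grid below the minimum supported size."""


class IncompleteGridError(VoxsrError, ValueError):
    """Patch aggregation received a patch set that does not cover its grid."""


class DivergenceError(VoxsrError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
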