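"""Exception and warning hierarchy for the coflow package.

All package errors derive from :class:`CoflowError` so callers (and the CLI)
can distinguish user-facing problems from genuine bugs.
"""


class CoflowError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CoflowError, ValueError):
    """An argument violates a physical or structural precondition."""


class DegenerateStreamError(InvalidInputError):
    """Interface fraction at 0 or 1: one of the two streams has vanished."""


class UnderdampedError(CoflowError):
    """Characteristic discriminant is negative; the lumped model assumes an
    overdamped (two real decay rates) response."""


class RepeatedRootError(CoflowError):
    """The two decay rates coincide; the two-mode analysis requires
    distinguishable eigenvalues (compliances of very different magnitude)."""


class NonIdentifiableError(CoflowError):
    """The eigenvalue sum/product system has no real solution for the
    requested unknowns."""


class ModelInconsistencyError(CoflowError):
    """A real solution exists but violates physicality (positivity or the
    ordering C1 < C2)."""


class NoRootError(CoflowError):
    """No steady interface exists in the correction-factor validity range."""


class MultipleRootsError(CoflowError):
    """The steady-state equation has several roots in the validity range."""

    def __init__(self, roots):
        self.roots = list(roots)
        super().__init__(
            f"steady-state equation has {len(self.roots)} roots in the "
            f"validity range: {self.roots}"
        )


class InsufficientDataError(CoflowError):
    """A window or fit does not have enough samples."""


class FitError(CoflowError):
    """Nonlinear or polynomial regression failed."""


class SegmentationError(CoflowError):
    """Image thresholding failed (e.g. constant or unimodal frame)."""


class ResolutionError(InvalidInputError):
    """Requested feature is below the pixel resolution."""


class ConfigError(CoflowError):
    """Configuration file invalid; message itemizes the violations."""


class ParseError(CoflowError):
    """Malformed tabular input; message carries the offending line number."""


class PipelineStageError(CoflowError):
    """An analysis stage failed; identifies the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class ValidityWarning(UserWarning):
    """Quantity evaluated outside the model's stated validity range."""


class ModelAssumptionWarning(UserWarning):
    """A modelling assumption (e.g. shallow-channel aspect ratio) is
    violated; results may be biased."""
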