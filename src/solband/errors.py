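"""Exception hierarchy for solband.

All package-specific failures derive from :class:`SolbandError` so callers can
catch everything the pipeline may raise with a single clause.
"""


class SolbandError(Exception):
    """Base class for all solband errors."""


class InvalidModelError(SolbandError):
    """The linkage model violates a structural invariant (e.g. mass <= 0)."""


class ParameterError(SolbandError, ValueError):
    """An argument is outside its documented domain."""


class StoParseError(SolbandError):
    """A storage (STO/MOT) file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DataError(SolbandError):
    """Input data violate a contract (e.g. non-monotone time column)."""


class PeakDetectionError(SolbandError):
    """Fewer than two ground-reaction-force peaks could be located."""


class InfeasibleFrameError(SolbandError):
    """The per-frame equilibrium problem has no feasible activation vector."""

    def __init__(self, message: str, frame: int | None = None,
                 worst_dof: str | None = None):
        self.frame = frame
        self.worst_dof = worst_dof
        super().__init__(message)


class InfeasibleTrialError(SolbandError):
    """One or more frames of a trial failed to solve.

    Carries the partial solution (failed frames flagged ``converged=False``)
    so batch drivers can decide whether to keep or drop the sample.
    """

    def __init__(self, message: str, failing_frames: list[int],
                 partial_solution=None):
        self.failing_frames = failing_frames
        self.partial_solution = partial_solution
        super().__init__(message)


class BandQualityError(SolbandError):
    """Too many samples of a band run failed to solve."""


class DegenerateDataError(SolbandError):
    """A statistical test received degenerate input (e.g. all-zero diffs)."""
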