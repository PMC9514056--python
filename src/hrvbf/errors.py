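"""Exception hierarchy shared by the whole pipeline.

Every stage raises a subclass of :class:`HrvbfError` so that the pipeline
driver can attach stage and segment context while re-raising.
"""


class HrvbfError(Exception):
    """Base class for all package errors."""


class ParameterError(HrvbfError, ValueError):
    """An argument violated a documented invariant (names the invariant)."""


class CapacityError(HrvbfError, ValueError):
    """More artifacts / edits requested than the series can absorb."""


class ParseError(HrvbfError, ValueError):
    """A text input could not be parsed; message carries the line number."""


class FormatError(HrvbfError, ValueError):
    """A file parsed but violated a structural contract (ordering, spacing)."""


class DetectionError(HrvbfError, RuntimeError):
    """A detector found no usable activity (flat ECG, too few breaths)."""


class InsufficientDataError(HrvbfError, ValueError):
    """Not enough beats / intervals / coverage for the requested statistic."""


class CoverageError(HrvbfError, ValueError):
    """The recording does not cover the declared phase schedule."""


class ConvergenceError(HrvbfError, RuntimeError):
    """Iterative correction or model fitting failed to converge."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


class UndefinedMetricError(HrvbfError, ValueError):
    """A metric is undefined for this input (zero variance, no valid cycles).

    Callers that tabulate metrics catch this and record an explicit
    "undefined" marker with the reason; it is never coerced to 0.
    """

    def __init__(self, message, reason=None):
        super().__init__(message)
        self.reason = reason or message


class ModelError(HrvbfError, RuntimeError):
    """A statistical model could not be fit."""
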