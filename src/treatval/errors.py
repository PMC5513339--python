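"""Exception hierarchy.

Errors distinguish configuration problems (user input), fitting failures
(data-dependent, recoverable at the replicate level) and undefined metrics
(degenerate analysis sets, recorded as flags rather than crashes).
"""


class TreatvalError(Exception):
    """Base class for all package errors."""


class ConfigError(TreatvalError):
    """A scenario configuration failed to parse or violated an invariant."""


class FittingError(TreatvalError):
    """Maximum-likelihood fitting failed.

    Parameters
    ----------
    message : str
    iterations : int, optional
        Number of IRLS iterations performed before failure.
    """

    def __init__(self, message: str, iterations: int | None = None):
        super().__init__(message)
        self.iterations = iterations


class SeparationError(FittingError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class DegenerateOutcomeError(FittingError):
    """The outcome (or treatment indicator) is constant: nothing to fit."""


class PositivityError(TreatvalError):
    """An untreated individual has estimated treatment probability 1.

    The inverse-probability weight 1/(1-PS) is infinite; the positivity
    assumption is violated at this observation.
    """

    def __init__(self, message: str, ps: float | None = None):
        super().__init__(message)
        self.ps = ps


class UndefinedMetricError(TreatvalError):
    """A performance metric is undefined on this analysis set.

    E.g. the c-index with no events or no non-events carrying positive
    weight. At the replicate level this is recorded as a flag, not a
    failure.
    """
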