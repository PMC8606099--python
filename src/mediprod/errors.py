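"""Exception and warning hierarchy for mediprod."""


class MediationError(Exception):
    """Base class for all mediprod errors."""


class FitError(MediationError):
    """A regression fit failed."""


class ConvergenceError(FitError):
    """Iterative fitting did not converge within the iteration budget."""


class SeparationError(FitError):
    """Logistic coefficients diverged, indicating (quasi-)separation."""


class RankDeficiencyError(FitError):
    """The design matrix is rank deficient.

    Carries the names of the offending (collinear) columns when known.
    """

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns else ()


class DegenerateMediatorError(FitError):
    """The mediator residual variance is zero."""


class UndefinedMPError(MediationError):
    """MP = NIE/TE requested with |TE| below tolerance."""


class QuadratureError(MediationError):
    """Nonfinite intermediate in the logistic-normal quadrature."""


class SolverError(MediationError):
    """A coefficient calibration root-find failed."""


class BootstrapError(MediationError):
    """Bootstrap interval could not be formed (too many failed resamples)."""


class DegenerateSummaryError(MediationError):
    """Simulation summary undefined (zero empirical variance)."""


class LinearPredictorClipWarning(UserWarning):
    """A linear predictor exceeded +/-700 and was clipped before exp()."""


class ClosedFormMismatchWarning(UserWarning):
    """Closed-form cross-check disagreed with the enumeration beyond tolerance."""
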