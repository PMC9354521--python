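"""Exception types raised across the model pipeline."""


class MesoCEAError(Exception):
    """Base class for all package-specific errors."""


class InvalidDistributionError(MesoCEAError, ValueError):
    """Survival-law parameters violate positivity/support constraints."""


class ReconstructionInfeasibleError(MesoCEAError, ValueError):
    """Digitized curve and risk table cannot be reconciled.

    Carries the index of the offending risk-table interval in ``interval``.
    """

    def __init__(self, message: str, interval: int | None = None):
        super().__init__(message)
        self.interval = interval


class InsufficientDataError(MesoCEAError, ValueError):
    """Too few events to fit a censored likelihood (need >= 2)."""


class IncomparableFitsError(MesoCEAError, ValueError):
    """Information-criterion comparison across fits on different data."""


class FitConvergenceError(MesoCEAError, RuntimeError):
    """Censored MLE optimiser failed to converge; carries optimizer detail."""


class InfeasibleMomentsError(MesoCEAError, ValueError):
    """No beta distribution has the requested mean/sd (sd^2 >= m(1-m))."""


class UndefinedICERError(MesoCEAError, ZeroDivisionError):
    """Incremental effect is numerically zero; the ratio is undefined."""


class ThresholdNotAchievableError(MesoCEAError, ValueError):
    """Even a 100% price cut leaves the ICER above the WTP threshold."""


class UnknownParameterError(MesoCEAError, KeyError):
    """Sensitivity-analysis parameter name has no model binding."""


class ConfigError(MesoCEAError, ValueError):
    """Configuration file failed schema validation."""
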