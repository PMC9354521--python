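"""Parametric survival laws used for overall- and progression-free-survival
extrapolation.

Three two-parameter families cover the fitted base case: Weibull, log-normal
and log-logistic.  Time is measured in **months** throughout this layer (the
fitted chemotherapy OS scale, 14.1088, reproduces the trial's 14.1-month
median survival, which pins the unit); the cohort engine converts its 3-week
cycle to months as 21/30.4375.

All quantities are closed-form:

    Weibull        S(t) = exp(-(t/scale)^shape)
    log-normal     S(t) = 1 - Phi((ln t - meanlog)/sdlog)
    log-logistic   S(t) = 1 / (1 + (t/scale)^shape)

``p1`` is the Weibull/log-logistic shape or the log-normal ``meanlog`` (the
only parameter allowed to be negative); ``p2`` is the scale in months or the
log-normal ``sdlog``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
from scipy import integrate
from scipy.special import erf, erfinv

from .errors import InvalidDistributionError

# Survival values are floored here before forming conditional ratios, so a
# numerically exhausted state yields transition probability 1 rather than NaN.
SURVIVAL_FLOOR = 1e-300


class Family(str, Enum):
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


def _norm_sf(z):
    # 1 - Phi(z) via the error function (vectorised)
    return 0.5 * (1.0 - erf(np.asarray(z) / math.sqrt(2.0)))


@dataclass(frozen=True)
class ParametricDistribution:
    """A survival law ``(family, p1, p2)`` with time in months."""

    family: Family
    p1: float
    p2: float

    def __post_init__(self):
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if not (np.isfinite(self.p1) and np.isfinite(self.p2)):
            raise InvalidDistributionError("parameters must be finite")
        if self.p2 <= 0:
            raise InvalidDistributionError(
                f"{fam.value}: scale/sdlog must be > 0, got {self.p2}"
            )
        if fam is not Family.LOGNORMAL and self.p1 <= 0:
            raise InvalidDistributionError(
                f"{fam.value}: shape must be > 0, got {self.p1}"
            )

    # -- core quantities ---------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array ``t`` (months); raises on negative t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise InvalidDistributionError("survival time must be >= 0")
        if self.family is Family.WEIBULL:
            out = np.exp(-((t / self.p2) ** self.p1))
        elif self.family is Family.LOGLOGISTIC:
            out = 1.0 / (1.0 + (t / self.p2) ** self.p1)
        else:  # log-normal; S(0) = 1 by continuity
            with np.errstate(divide="ignore"):
                logt = np.log(np.where(t > 0, t, 1.0))
            out = np.where(t > 0, _norm_sf((logt - self.p1) / self.p2), 1.0)
        return out if out.ndim else float(out)

    def density(self, t):
        """f(t) = -dS/dt."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise InvalidDistributionError("time must be >= 0")
        tpos = np.where(t > 0, t, np.nan)
        if self.family is Family.WEIBULL:
            k, lam = self.p1, self.p2
            out = (k / lam) * (tpos / lam) ** (k - 1.0) * np.exp(-((tpos / lam) ** k))
        elif self.family is Family.LOGLOGISTIC:
            k, lam = self.p1, self.p2
            x = (tpos / lam) ** k
            out = (k / tpos) * x / (1.0 + x) ** 2
        else:
            z = (np.log(tpos) - self.p1) / self.p2
            out = np.exp(-0.5 * z * z) / (tpos * self.p2 * math.sqrt(2 * math.pi))
        out = np.where(t > 0, out, 0.0)
        return out if out.ndim else float(out)

    def median(self) -> float:
        """Closed-form median survival time (months)."""
        if self.family is Family.WEIBULL:
            return self.p2 * math.log(2.0) ** (1.0 / self.p1)
        if self.family is Family.LOGNORMAL:
            return math.exp(self.p1)
        return self.p2  # log-logistic

    def mean(self) -> float:
        """Unrestricted mean; inf for a log-logistic with shape <= 1."""
        if self.family is Family.WEIBULL:
            return self.p2 * math.gamma(1.0 + 1.0 / self.p1)
        if self.family is Family.LOGNORMAL:
            return math.exp(self.p1 + 0.5 * self.p2**2)
        if self.p1 <= 1.0:
            return math.inf
        b = math.pi / self.p1
        return self.p2 * b / math.sin(b)

    # -- model plumbing ----------------------------------------------------

    def transition_probability(self, t: float, delta: float) -> float:
        """Per-cycle event probability ``1 - S(t+delta)/S(t)``.

        A state whose survival has numerically vanished transitions with
        probability 1 (the cohort fraction there is already exhausted).
        """
        if t < 0 or delta <= 0:
            raise InvalidDistributionError("need t >= 0 and delta > 0")
        s0 = max(float(self.survival(t)), SURVIVAL_FLOOR)
        s1 = max(float(self.survival(t + delta)), SURVIVAL_FLOOR)
        if s0 <= SURVIVAL_FLOOR:
            return 1.0
        return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))

    def restricted_mean(self, horizon: float) -> float:
        """Integral of S over [0, horizon] (months) by adaptive quadrature."""
        if horizon <= 0:
            if horizon == 0:
                return 0.0
            raise InvalidDistributionError("horizon must be > 0")
        val, _ = integrate.quad(
            lambda u: float(self.survival(u)), 0.0, horizon, limit=200
        )
        return val

    def ppf(self, q):
        """Inverse CDF: time below which a fraction ``q`` has had the event."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise InvalidDistributionError("quantile must lie in [0, 1)")
        if self.family is Family.WEIBULL:
            out = self.p2 * (-np.log1p(-q)) ** (1.0 / self.p1)
        elif self.family is Family.LOGLOGISTIC:
            out = self.p2 * (q / (1.0 - q)) ** (1.0 / self.p1)
        else:
            out = np.exp(self.p1 + self.p2 * math.sqrt(2.0) * erfinv(2.0 * q - 1.0))
        return out if out.ndim else float(out)

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """``n`` i.i.d. event times by inverse-CDF; reproducible per seed."""
        if n < 1:
            raise InvalidDistributionError("need n >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        return np.asarray(self.ppf(rng.uniform(size=n)))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family.value, "parameters": [self.p1, self.p2]}

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricDistribution":
        p = d["parameters"]
        return cls(Family(d["family"]), float(p[0]), float(p[1]))


def survival_table(
    dist: ParametricDistribution, times: Iterable[float]
) -> "np.ndarray":
    """S(t) on a user grid, as an (n, 2) array of (t, S) rows for CSV export."""
    t = np.asarray(list(times), dtype=float)
    return np.column_stack([t, dist.survival(t)])
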