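"""Pseudo individual-patient data (IPD) from digitized Kaplan-Meier curves,
and censored maximum-likelihood fitting of parametric survival families.

The reconstruction is the risk-table-constrained algorithm of Guyot et al.:
within each interval between consecutive numbers-at-risk, an integer
censoring count is solved for so that the implied number at risk at the next
risk-table time matches the published one, censorings are spread uniformly
within the interval, and event counts at each digitized time are recovered
from the Kaplan-Meier ratios.  The KM curve recomputed from the output
matches the input survival probabilities up to the rounding forced by
integer counts (within 1/n for n initially at risk).

After the last risk-table time no further censoring is assumed; patients
still at risk at the last digitized time are administratively censored
there.

Fitting maximises the right-censored log-likelihood
``sum_events ln f(t) + sum_censored ln S(t)`` for the Weibull, log-normal
and log-logistic families (via lifelines' univariate fitters), and model
choice uses AIC (= 2k - 2 ln L) or BIC (= k ln n - 2 ln L) with k = 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FitConvergenceError,
    IncomparableFitsError,
    InsufficientDataError,
    ReconstructionInfeasibleError,
)
from .survival import Family, ParametricDistribution

FAMILY_ORDER = (Family.WEIBULL, Family.LOGNORMAL, Family.LOGLOGISTIC)


@dataclass
class DigitizedCurve:
    """Digitized KM coordinates plus the numbers-at-risk table."""

    times: np.ndarray
    surv: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if len(self.times) != len(self.surv):
            raise ValueError("times and surv must have equal length")
        if len(self.risk_times) != len(self.n_at_risk):
            raise ValueError("risk_times and n_at_risk must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(self.surv > 1.0) or np.any(self.surv < 0.0):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")

    def isotonic(self) -> "DigitizedCurve":
        """Copy with survival clipped non-increasing (running minimum) —
        hand-digitized points can invert slightly."""
        return DigitizedCurve(
            self.times,
            np.minimum.accumulate(self.surv),
            self.risk_times,
            self.n_at_risk,
        )


@dataclass
class PseudoIPD:
    """Reconstructed (time, event) records; event 1 = death, 0 = censored."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) != len(self.event):
            raise ValueError("time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})


@dataclass
class FitResult:
    dist: ParametricDistribution
    loglik: float
    aic: float
    bic: float
    n: int
    tie: bool = False


# ---------------------------------------------------------------------------
# Guyot reconstruction
# ---------------------------------------------------------------------------


def guyot_reconstruct(curve: DigitizedCurve) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized curve plus risk table."""
    curve = curve.isotonic()
    t = curve.times
    s = curve.surv
    # anchor the curve at (0, 1)
    if len(t) == 0 or t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    if s[0] < 1.0:
        raise ReconstructionInfeasibleError("curve must start at survival 1")
    rt = curve.risk_times
    nrisk = curve.n_at_risk
    if len(rt) == 0:
        raise ReconstructionInfeasibleError("need at least one risk-table entry")

    # digitized indices belonging to each risk interval [rt[i], rt[i+1])
    edges = np.concatenate([rt, [np.inf]])
    interval_of = np.searchsorted(edges, t, side="right") - 1
    if np.any(interval_of < 0):
        raise ReconstructionInfeasibleError(
            "digitized times precede the first risk-table time", interval=0
        )

    event_times: list[float] = []
    censor_times: list[float] = []
    n_cur = int(nrisk[0])
    km_cur = 1.0

    for i in range(len(rt)):
        idx = np.where(interval_of == i)[0]
        lo = rt[i]
        hi = rt[i + 1] if i + 1 < len(rt) else (t[-1] if len(t) else lo)
        if i + 1 < len(rt):
            target_next = int(nrisk[i + 1])
            _, ev, cen, n_end, km_end = _solve_interval(
                t, s, idx, lo, hi, n_cur, km_cur, target_next
            )
            # a small shortfall is digitization noise over-spending the risk
            # set (tolerated, best effort); a gross one means the curve
            # implies more events than patients at risk allow
            if target_next - n_end > max(2, 0.05 * int(nrisk[0])):
                raise ReconstructionInfeasibleError(
                    f"{target_next} at risk published entering interval "
                    f"{i + 1} but only {n_end} remain reconstructable",
                    interval=i,
                )
        else:
            # final interval: assume no censoring beyond the last risk time
            ev, cen, n_end, km_end = _allocate_interval(
                t, s, idx, lo, hi, n_cur, km_cur, 0
            )
        event_times.extend(ev)
        censor_times.extend(cen)
        n_cur, km_cur = n_end, km_end

    # survivors at the end of follow-up are administratively censored
    last_time = t[-1] if len(t) else rt[-1]
    censor_times.extend([float(last_time)] * n_cur)

    times = np.array(event_times + censor_times)
    events = np.array([1] * len(event_times) + [0] * len(censor_times))
    order = np.argsort(times, kind="stable")
    ipd = PseudoIPD(times[order], events[order])
    if ipd.n > int(nrisk[0]):
        raise ReconstructionInfeasibleError(
            f"reconstructed {ipd.n} patients from {int(nrisk[0])} at risk"
        )
    return ipd


def _solve_interval(t, s, idx, lo, hi, n_enter, km_enter, target_next):
    """Find the integer censoring count whose implied number at risk at the
    next risk time matches the published one (monotone in the count)."""
    best = None
    for c in range(n_enter + 1):
        ev, cen, n_end, km_end = _allocate_interval(
            t, s, idx, lo, hi, n_enter, km_enter, c
        )
        diff = n_end - target_next
        if best is None or abs(diff) < abs(best[0]):
            best = (diff, c, ev, cen, n_end, km_end)
        if diff == 0:
            break
        if diff < 0:  # already too few at risk; more censoring only worsens it
            break
    diff, c, ev, cen, n_end, km_end = best
    return c, ev, cen, n_end, km_end


def _allocate_interval(t, s, idx, lo, hi, n_enter, km_enter, n_censor):
    """Distribute ``n_censor`` censorings uniformly over (lo, hi) and recover
    event counts at each digitized time from the KM ratios."""
    width = max(hi - lo, 0.0)
    if n_censor > 0 and width > 0:
        cen_times = lo + (np.arange(1, n_censor + 1) - 0.5) / n_censor * width
    else:
        cen_times = np.array([lo] * n_censor)
    events: list[float] = []
    n_cur = n_enter
    km_cur = km_enter
    cen_used = 0
    for j in idx:
        # censorings preceding this digitized time leave the risk set first
        while cen_used < n_censor and cen_times[cen_used] < t[j] and n_cur > 0:
            cen_used += 1
            n_cur -= 1
        if n_cur <= 0 or km_cur <= 0:
            break
        d = int(round(n_cur * (1.0 - s[j] / km_cur)))
        d = min(max(d, 0), n_cur)
        if d > 0:
            km_cur *= 1.0 - d / n_cur
            events.extend([float(t[j])] * d)
            n_cur -= d
    n_cur -= n_censor - cen_used  # censorings after the last digitized point
    n_cur = max(n_cur, 0)
    return events, list(map(float, cen_times[:n_censor])), n_cur, km_cur


def km_curve_from_ipd(ipd: PseudoIPD, at_times: np.ndarray) -> np.ndarray:
    """Product-limit estimate from (time, event) records, evaluated at
    ``at_times`` (events precede censorings at ties)."""
    order = np.lexsort((1 - ipd.event, ipd.time))
    times = ipd.time[order]
    events = ipd.event[order]
    uniq = np.unique(times[events == 1])
    s = 1.0
    step_t, step_s = [0.0], [1.0]
    for u in uniq:
        n_at = np.sum(times >= u)  # ties: events counted before censorings
        d = np.sum((times == u) & (events == 1))
        if n_at > 0:
            s *= 1.0 - d / n_at
        step_t.append(u)
        step_s.append(s)
    step_t = np.asarray(step_t)
    step_s = np.asarray(step_s)
    pos = np.searchsorted(step_t, at_times, side="right") - 1
    return step_s[np.clip(pos, 0, len(step_s) - 1)]


# ---------------------------------------------------------------------------
# Censored maximum-likelihood fitting
# ---------------------------------------------------------------------------

_LIFELINES_FITTERS = {
    Family.WEIBULL: ("WeibullFitter", "rho_", "lambda_"),
    Family.LOGNORMAL: ("LogNormalFitter", "mu_", "sigma_"),
    Family.LOGLOGISTIC: ("LogLogisticFitter", "beta_", "alpha_"),
}


def censored_loglik(dist: ParametricDistribution, ipd: PseudoIPD) -> float:
    """Right-censored log-likelihood of the data under ``dist``."""
    t = np.maximum(ipd.time, 1e-12)
    f = np.maximum(dist.density(t), 1e-300)
    s = np.maximum(dist.survival(t), 1e-300)
    return float(
        np.sum(np.where(ipd.event == 1, np.log(f), np.log(s)))
    )


def fit_parametric(ipd: PseudoIPD, family: Family | str) -> FitResult:
    """Censored MLE of one family, with AIC/BIC (k = 2 parameters)."""
    import lifelines

    family = Family(family)
    if ipd.n_events < 2:
        raise InsufficientDataError(
            f"need >= 2 events to fit, got {ipd.n_events}"
        )
    cls_name, p1_attr, p2_attr = _LIFELINES_FITTERS[family]
    fitter = getattr(lifelines, cls_name)()
    t = np.maximum(ipd.time, 1e-9)  # fitters need strictly positive times
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(t, event_observed=ipd.event)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise FitConvergenceError(f"{family.value} fit failed: {exc}") from exc
    dist = ParametricDistribution(
        family, float(getattr(fitter, p1_attr)), float(getattr(fitter, p2_attr))
    )
    ll = censored_loglik(dist, ipd)
    k = 2
    aic = 2 * k - 2 * ll
    bic = k * math.log(ipd.n) - 2 * ll
    return FitResult(dist, ll, aic, bic, ipd.n)


def fit_all_families(ipd: PseudoIPD) -> list[FitResult]:
    return [fit_parametric(ipd, fam) for fam in FAMILY_ORDER]


def select_distribution(fits: list[FitResult], criterion: str = "aic") -> FitResult:
    """Minimum-AIC/BIC fit; ties broken by family order (Weibull, log-normal,
    log-logistic) and flagged on the returned result."""
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    if not fits:
        raise ValueError("empty fit list")
    if len({f.n for f in fits}) > 1:
        raise IncomparableFitsError(
            "information criteria compare fits on the same data only"
        )
    order = {fam: i for i, fam in enumerate(FAMILY_ORDER)}
    ranked = sorted(
        fits, key=lambda f: (getattr(f, criterion), order[f.dist.family])
    )
    best = ranked[0]
    tie = any(
        getattr(f, criterion) == getattr(best, criterion)
        for f in fits
        if f is not best
    )
    return FitResult(best.dist, best.loglik, best.aic, best.bic, best.n, tie=tie)


def fits_table(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [f.dist.family.value for f in fits],
            "p1": [f.dist.p1 for f in fits],
            "p2": [f.dist.p2 for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
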