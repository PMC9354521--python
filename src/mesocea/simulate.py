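"""Synthetic trial data: individual patient survival times from known
parametric laws, their Kaplan-Meier step functions with numbers-at-risk
tables, and noisy "digitized" coordinate extractions of those curves.

This stands in for the trial figures the base-case laws were fitted from
(which are not redistributable), so the digitize -> reconstruct -> fit
pipeline is testable end to end.  The default scenarios are the four
published distributions at the trial arm sizes (n = 303 and 302) with
administrative censoring at 36 months, approximating the trial's ~30-month
median follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import DigitizedCurve, PseudoIPD
from .survival import ParametricDistribution


@dataclass(frozen=True)
class Censoring:
    """``none``, ``administrative`` (cutoff at ``value`` months) or
    ``exponential`` (random censoring with rate ``value`` per month)."""

    kind: str = "none"
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "administrative", "exponential"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind != "none" and self.value <= 0:
            raise ValueError("censoring parameter must be positive")


@dataclass(frozen=True)
class SimulationScenario:
    true_dist: ParametricDistribution
    n_patients: int
    censoring: Censoring = Censoring()
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


def simulate_ipd(scenario: SimulationScenario) -> PseudoIPD:
    """Observed (time, event) records under the scenario's censoring scheme."""
    rng = np.random.default_rng(scenario.seed)
    event_t = scenario.true_dist.sample(scenario.n_patients, rng)
    cen = scenario.censoring
    if cen.kind == "none":
        return PseudoIPD(event_t, np.ones(scenario.n_patients, dtype=int))
    if cen.kind == "administrative":
        censor_t = np.full(scenario.n_patients, cen.value)
    else:
        censor_t = rng.exponential(1.0 / cen.value, size=scenario.n_patients)
    observed = np.minimum(event_t, censor_t)
    flag = (event_t <= censor_t).astype(int)
    return PseudoIPD(observed, flag)


def km_estimate(ipd: PseudoIPD, risk_times) -> DigitizedCurve:
    """Product-limit step function with numbers at risk at ``risk_times``.

    Ties follow the standard convention: events precede censorings.
    """
    if ipd.n_events < 1:
        raise ValueError("need at least one event for a KM estimate")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, event_observed=ipd.event)
    sf = kmf.survival_function_
    event_times = np.unique(ipd.time[ipd.event == 1])
    surv = (
        sf.reindex(sf.index.union(event_times)).ffill().loc[event_times].to_numpy().ravel()
    )
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([(ipd.time >= rt).sum() for rt in risk_times], dtype=int)
    return DigitizedCurve(event_times, surv, risk_times, n_at_risk)


def perturb_digitization(
    curve: DigitizedCurve,
    noise_sd: float,
    grid_step: float | None = None,
    seed: int = 0,
) -> DigitizedCurve:
    """Emulate graph-digitizer error: resample the step curve on a pixel-like
    grid, jitter the survival reads with truncated Gaussian noise, and
    re-impose monotonicity.  The risk table passes through unchanged."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if grid_step is None:
        grid = curve.times.copy()
    else:
        grid = np.arange(grid_step, curve.times[-1] + grid_step / 2, grid_step)
    # step-function read: last digitized value at or before each grid time
    pos = np.searchsorted(curve.times, grid, side="right") - 1
    vals = np.where(pos >= 0, curve.surv[np.clip(pos, 0, None)], 1.0)
    if noise_sd > 0:
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=len(vals)), 0.0, 1.0)
    vals = np.minimum.accumulate(np.minimum(vals, 1.0))
    return DigitizedCurve(grid, vals, curve.risk_times, curve.n_at_risk)


def default_scenarios() -> dict[str, SimulationScenario]:
    """The four published base-case laws at the trial arm sizes."""
    from .model import CHEMO_OS, CHEMO_PFS, NIVO_IPI_OS, NIVO_IPI_PFS

    cen = Censoring("administrative", 36.0)
    return {
        "nivo_ipi_os": SimulationScenario(NIVO_IPI_OS, 303, cen, seed=11),
        "nivo_ipi_pfs": SimulationScenario(NIVO_IPI_PFS, 303, cen, seed=12),
        "chemo_os": SimulationScenario(CHEMO_OS, 302, cen, seed=13),
        "chemo_pfs": SimulationScenario(CHEMO_PFS, 302, cen, seed=14),
    }
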