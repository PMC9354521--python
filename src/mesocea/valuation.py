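"""Costing and utility layer: attaches per-cycle drug, monitoring,
adverse-event and subsequent-therapy costs plus health-state utilities to a
cohort trace and accumulates discounted totals per treatment arm.

All prices are 2021 US dollars per 3-week cycle (the shipped defaults are the
base-case price list; BSA 1.68 m^2 is the dosing constant behind them).
Utilities are per year alive in the state (0.65 progression-free, 0.47
progressed).  Adverse-event burdens are one-time, applied to the whole cohort
at model entry and lasting one cycle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTrace, ModelSettings, MONTHS_PER_YEAR, run_trace
from .survival import ParametricDistribution

_STATES = ("pfs", "pd", "death")


@dataclass
class CostInputs:
    """Per-cycle unit costs (USD, 2021) and the dosing BSA constant."""

    cisplatin: float = 48.6108
    carboplatin: float = 55.80288
    pemetrexed: float = 12832.512
    nivolumab: float = 18419.94
    ipilimumab: float = 11258.31
    laboratory_test: float = 157.5
    follow_up: float = 59.2
    administration: float = 69.81
    best_supportive_care: float = 117.1
    pembrolizumab: float = 21479.6
    vinorelbine: float = 227.2756
    body_surface_area: float = 1.68  # m^2, informational dose constant
    currency: str = "USD-2021"

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "currency":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"cost input {f.name!r} must be non-negative")

    def unit(self, name: str) -> float:
        if name == "platinum_blend":
            # 50/50 cisplatin/carboplatin mix (configurable via the two costs)
            return 0.5 * (self.cisplatin + self.carboplatin)
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown cost component {name!r}") from None


@dataclass
class UtilityInputs:
    u_pfs: float = 0.65
    u_pd: float = 0.47
    u_death: float = 0.0

    def __post_init__(self):
        for name in ("u_pfs", "u_pd", "u_death"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class AdverseEvent:
    """One grade >=3 adverse event: incidence risk, one-time management cost
    and one-cycle utility decrement (non-positive)."""

    name: str
    risk: float
    cost: float
    disutility: float

    def __post_init__(self):
        if not (0.0 <= self.risk <= 1.0):
            raise ValueError(f"AE {self.name}: risk must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError(f"AE {self.name}: cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"AE {self.name}: disutility must be <= 0")


@dataclass
class SubsequentTherapyMix:
    """Post-progression treatment mix; the remainder gets supportive care only."""

    p_immunotherapy: float
    p_chemotherapy: float
    immunotherapy_drug: str = "pembrolizumab"
    chemotherapy_drug: str = "vinorelbine"
    duration_cycles: int = 6

    def __post_init__(self):
        for name in ("p_immunotherapy", "p_chemotherapy"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_immunotherapy + self.p_chemotherapy > 1.0 + 1e-12:
            raise ValueError("subsequent-therapy probabilities exceed 1")
        if self.duration_cycles < 0:
            raise ValueError("duration_cycles must be >= 0")

    def per_cycle_cost(self, costs: CostInputs) -> float:
        return self.p_immunotherapy * costs.unit(
            self.immunotherapy_drug
        ) + self.p_chemotherapy * costs.unit(self.chemotherapy_drug)


@dataclass
class StrategySpec:
    """One treatment arm: survival laws, on-treatment regimen, AE profile and
    subsequent-therapy mix.

    ``on_treatment`` maps cost-component names to units delivered per cycle
    while progression-free (e.g. ``{"pemetrexed": 1, "cisplatin": 0.5,
    "carboplatin": 0.5}`` for the 50/50 platinum blend).
    ``max_treatment_cycles`` caps drug acquisition (None = treat while
    progression-free).
    """

    name: str
    os_dist: ParametricDistribution
    pfs_dist: ParametricDistribution
    on_treatment: dict[str, float]
    ae_profile: list[AdverseEvent] = field(default_factory=list)
    subsequent: SubsequentTherapyMix | None = None
    max_treatment_cycles: int | None = None

    def __post_init__(self):
        if self.max_treatment_cycles is not None and self.max_treatment_cycles < 0:
            raise ValueError("max_treatment_cycles must be >= 0 or None")

    def drug_cost_per_cycle(self, costs: CostInputs) -> float:
        return sum(q * costs.unit(nm) for nm, q in self.on_treatment.items())


@dataclass
class ArmResult:
    """Discounted totals per arm, with undiscounted twins."""

    name: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


def cycle_cost(
    strategy: StrategySpec, costs: CostInputs, state: str, cycle: int
) -> float:
    """Per-cycle USD cost of one occupant of ``state`` at cycle index ``cycle``.

    The PD figure is the cost while on subsequent therapy; ``accumulate``
    limits it to the configured number of post-progression cycles.
    """
    if state not in _STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {_STATES}")
    if state == "death":
        return 0.0
    if state == "pfs":
        cap = strategy.max_treatment_cycles
        drug = 0.0 if (cap is not None and cycle >= cap) else strategy.drug_cost_per_cycle(costs)
        return drug + costs.administration + costs.laboratory_test + costs.follow_up
    # PD
    sub = (
        strategy.subsequent.per_cycle_cost(costs) if strategy.subsequent else 0.0
    )
    return sub + costs.best_supportive_care + costs.follow_up


def cycle_utility(utilities: UtilityInputs, state: str) -> float:
    """Utility weight per year spent in ``state``."""
    if state not in _STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {_STATES}")
    return {"pfs": utilities.u_pfs, "pd": utilities.u_pd, "death": utilities.u_death}[
        state
    ]


def ae_burden(
    profile: list[AdverseEvent], settings: ModelSettings
) -> tuple[float, float]:
    """Expected one-time AE cost and QALY decrement for the whole cohort.

    The decrement applies each event's disutility for one cycle.
    """
    cost = sum(ae.risk * ae.cost for ae in profile)
    cycle_years = settings.cycle_months / MONTHS_PER_YEAR
    dqaly = sum(ae.risk * ae.disutility * cycle_years for ae in profile)
    return cost, dqaly


def _accumulate_weighted(
    trace: CohortTrace,
    strategy: StrategySpec,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
    weights: np.ndarray,
) -> tuple[float, float, float]:
    """(cost, ly, qaly) under the supplied discount weights."""
    t = trace.t_months
    dt = np.diff(t)
    cyc = settings.cycle_months
    n_int = len(dt)

    def interval_months(occ: np.ndarray) -> np.ndarray:
        ow = occ * weights
        if settings.half_cycle:
            return 0.5 * (ow[:-1] + ow[1:]) * dt
        return ow[:-1] * dt

    pfs_m = interval_months(trace.pfs)   # discounted occupancy-months / interval
    pd_m = interval_months(trace.pd)
    alive_m = pfs_m + pd_m

    # ---- life-years and QALYs
    ly = alive_m.sum() / MONTHS_PER_YEAR
    qaly = (utilities.u_pfs * pfs_m.sum() + utilities.u_pd * pd_m.sum()) / MONTHS_PER_YEAR

    # ---- PFS costs: monitoring everywhere, drug while uncapped
    monitor_rate = (costs.administration + costs.laboratory_test + costs.follow_up) / cyc
    total = monitor_rate * pfs_m.sum()
    drug_rate = strategy.drug_cost_per_cycle(costs) / cyc
    cap = strategy.max_treatment_cycles
    if cap is None:
        total += drug_rate * pfs_m.sum()
    else:
        total += drug_rate * pfs_m[: min(cap, n_int)].sum()

    # ---- PD costs: supportive care for everyone, subsequent regimen only for
    # the fraction within `duration_cycles` of progressing (inflow queue)
    bsc_rate = (costs.best_supportive_care + costs.follow_up) / cyc
    total += bsc_rate * pd_m.sum()
    if strategy.subsequent is not None and strategy.subsequent.duration_cycles > 0:
        d = strategy.subsequent.duration_cycles
        inflow = np.maximum(0.0, -np.diff(trace.pfs))  # progressions per interval
        queue = np.convolve(inflow, np.ones(d))[:n_int]  # recent-progressor pool
        pd_mid = 0.5 * (trace.pd[:-1] + trace.pd[1:])
        on_sub = np.minimum(pd_mid, queue)
        w_mid = 0.5 * (weights[:-1] + weights[1:])
        sub_rate = strategy.subsequent.per_cycle_cost(costs) / cyc
        total += sub_rate * (on_sub * w_mid * dt).sum()

    # ---- one-time AE burden at entry (discount weight 1 at t = 0)
    ae_cost, ae_dqaly = ae_burden(strategy.ae_profile, settings)
    total += ae_cost
    qaly += ae_dqaly

    return float(total), float(ly), float(qaly)


def accumulate(
    trace: CohortTrace,
    strategy: StrategySpec,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> ArmResult:
    """Discounted and undiscounted cost/LY/QALY totals for one arm."""
    disc = _accumulate_weighted(
        trace, strategy, costs, utilities, settings, trace.disc_weight
    )
    ones = np.ones_like(trace.disc_weight)
    undisc = _accumulate_weighted(trace, strategy, costs, utilities, settings, ones)
    return ArmResult(strategy.name, *disc, *undisc)


def run_arm(
    strategy: StrategySpec,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
    trace: CohortTrace | None = None,
) -> ArmResult:
    """Convenience wrapper: trace the cohort (unless given) and value it."""
    if trace is None:
        trace = run_trace(strategy.os_dist, strategy.pfs_dist, settings)
    return accumulate(trace, strategy, costs, utilities, settings)
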