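"""Incremental cost-effectiveness comparison: deltas, ICERs, net monetary
benefit and the drug-price-reduction threshold search.

The willingness-to-pay default, $207,659 per QALY, is three times 2021 US GDP
per capita ($69,231 x 3), the conventional WHO-style threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import ThresholdNotAchievableError, UndefinedICERError
from .valuation import ArmResult

_EFFECT_EPS = 1e-12


@dataclass(frozen=True)
class WTPContext:
    wtp_per_qaly: float = 207659.0

    def __post_init__(self):
        if self.wtp_per_qaly <= 0:
            raise ValueError("WTP must be positive")


@dataclass
class IncrementalResult:
    """Intervention-minus-comparator deltas and the resulting ratios.

    ICER fields are ``nan`` when the corresponding effect delta is zero;
    ``dominant`` / ``dominated`` flag strict dominance (cheaper & more
    effective, or dearer & less effective, on QALYs).
    """

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float
    icer_per_ly: float
    dominant: bool
    dominated: bool


def incremental(
    intervention: ArmResult, comparator: ArmResult
) -> IncrementalResult:
    """Deltas and ICERs from unrounded arm totals."""
    dc = intervention.cost - comparator.cost
    dly = intervention.ly - comparator.ly
    dq = intervention.qaly - comparator.qaly
    icer_q = dc / dq if abs(dq) > _EFFECT_EPS else math.nan
    icer_ly = dc / dly if abs(dly) > _EFFECT_EPS else math.nan
    dominant = dc < 0 and dq > 0
    dominated = dc > 0 and dq < 0
    return IncrementalResult(dc, dly, dq, icer_q, icer_ly, dominant, dominated)


def icer_per_qaly(intervention: ArmResult, comparator: ArmResult) -> float:
    """ΔC/ΔQALY, raising when the effect delta is numerically zero."""
    inc = incremental(intervention, comparator)
    if math.isnan(inc.icer_per_qaly):
        raise UndefinedICERError("incremental QALYs are zero; ICER undefined")
    return inc.icer_per_qaly


def nmb(result: ArmResult, wtp: WTPContext) -> float:
    """Net monetary benefit, WTP x QALY - cost (discounted)."""
    return wtp.wtp_per_qaly * result.qaly - result.cost


def is_cost_effective(inc: IncrementalResult, wtp: WTPContext) -> bool:
    """Verdict for the intervention vs the comparator at the threshold.

    Equivalent to the sign of the incremental NMB:
    ``wtp * dQALY - dCost > 0``.
    """
    return wtp.wtp_per_qaly * inc.delta_qaly - inc.delta_cost > 0


def price_threshold_search(
    icer_at_reduction: Callable[[float], float],
    wtp: WTPContext,
    grid: float = 0.001,
) -> tuple[float, float]:
    """Smallest drug-price reduction fraction bringing the ICER to the WTP.

    ``icer_at_reduction(r)`` must re-run the full base case with the
    reducible cost components multiplied by ``(1 - r)`` and return the ICER
    per QALY.  Bisection on ``r`` in [0, 1], then snapped up to the ``grid``
    resolution (default 0.1%).  Returns ``(r, icer_at_r)``; ``r = 0`` when
    the base case is already below the threshold.
    """
    target = wtp.wtp_per_qaly
    if icer_at_reduction(0.0) <= target:
        return 0.0, icer_at_reduction(0.0)
    if icer_at_reduction(1.0) > target:
        raise ThresholdNotAchievableError(
            "ICER exceeds the threshold even with a 100% price reduction"
        )
    lo, hi = 0.0, 1.0  # ICER(lo) > target >= ICER(hi)
    while hi - lo > grid / 8.0:
        mid = 0.5 * (lo + hi)
        if icer_at_reduction(mid) <= target:
            hi = mid
        else:
            lo = mid
    r = math.ceil(hi / grid - 1e-9) * grid
    return r, icer_at_reduction(r)
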