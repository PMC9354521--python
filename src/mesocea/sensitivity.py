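"""Deterministic (one-way, tornado) and probabilistic (second-order Monte
Carlo) sensitivity analysis.

One-way: every uncertain input is swung to 80% and 120% of its base value
with everything else held at base, and the resulting ICER range is ranked.

Probabilistic: each iteration redraws every uncertain input from its
assigned distribution — gamma for costs, beta for probabilities, utilities
and (on the magnitude) disutilities, both parameterised by method of moments
from the base value and an SD of 20% of base — and re-runs both arms.  The
four fitted survival parameter sets are held fixed (they are point estimates
from curve fitting, with no published uncertainty).  Draws use one named
generator per run; parameters are drawn in list order, so seeds are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cea import WTPContext
from .errors import InfeasibleMomentsError, UnknownParameterError
from .model import CEAOutcome, DecisionModel

_MAX_REDRAWS = 100


@dataclass
class ParameterSpec:
    """One uncertain model input.

    ``name`` is a model-parameter path understood by
    ``DecisionModel.with_parameters``; ``low``/``high`` default to +-20% of
    base; ``psa_family`` is ``beta`` (quantities in [0,1], or magnitudes of
    disutilities), ``gamma`` (costs) or ``fixed``; ``sd`` defaults to 20% of
    base.
    """

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    psa_family: str = "fixed"
    sd: float | None = None

    def __post_init__(self):
        if self.low is None:
            self.low = 0.8 * self.base
        if self.high is None:
            self.high = 1.2 * self.base
        lo, hi = min(self.low, self.high), max(self.low, self.high)
        if not (lo <= self.base <= hi):
            raise ValueError(f"{self.name}: base must lie within [low, high]")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown PSA family {self.psa_family!r}")
        if self.sd is None:
            self.sd = 0.2 * abs(self.base)

    def draw(self, rng: np.random.Generator) -> float:
        if self.psa_family == "fixed" or self.sd == 0:
            return self.base
        mag = abs(self.base)
        sign = -1.0 if self.base < 0 else 1.0
        if self.psa_family == "gamma":
            shape, scale = gamma_from_mean_sd(mag, self.sd)
            return sign * rng.gamma(shape, scale)
        a, b = beta_from_mean_sd(mag, self.sd)
        return sign * rng.beta(a, b)


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class PSAOutput:
    """Per-iteration incremental (cost, QALY) pairs from the Monte Carlo."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_iterations: int
    seed: int

    def nmb_positive_fraction(self, wtp: WTPContext) -> float:
        """Fraction of iterations where the intervention is cost-effective."""
        dnmb = wtp.wtp_per_qaly * self.delta_qaly - self.delta_cost
        return float(np.mean(dnmb > 0))


# -- method-of-moments distribution builders --------------------------------


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the requested mean and SD.

    Requires 0 < mean < 1 and sd^2 < mean(1-mean).
    """
    if not (0.0 < mean < 1.0):
        raise InfeasibleMomentsError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise InfeasibleMomentsError("sd must be positive")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"no beta distribution has mean {mean} and sd {sd} "
            f"(need sd^2 < mean(1-mean) = {mean * (1 - mean):.6g})"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the requested mean and SD."""
    if mean <= 0 or sd <= 0:
        raise InfeasibleMomentsError("gamma mean and sd must be positive")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


# -- deterministic sweep -----------------------------------------------------


def one_way_sweep(
    params: Sequence[ParameterSpec], model: DecisionModel
) -> list[TornadoEntry]:
    """ICER at each parameter's low/high with the others at base, ranked by
    descending spread."""
    traces = model.traces()  # survival inputs never vary in the sweep
    entries = []
    for p in params:
        icers = []
        for v in (p.low, p.high):
            out = model.with_parameters({p.name: v}).run(traces)
            icers.append(out.incremental.icer_per_qaly)
        entries.append(TornadoEntry(p.name, icers[0], icers[1]))
    entries.sort(key=lambda e: -e.spread)
    return entries


# -- probabilistic analysis ---------------------------------------------------


def psa_run(
    params: Sequence[ParameterSpec],
    model: DecisionModel,
    n: int = 10_000,
    seed: int = 0,
) -> PSAOutput:
    """Second-order Monte Carlo over the uncertain inputs.

    Infeasible draws (violating a type invariant on assignment) are redrawn
    up to a bounded number of times before raising.
    """
    rng = np.random.default_rng(seed)
    traces = model.traces()
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        for attempt in range(_MAX_REDRAWS):
            draws = {p.name: p.draw(rng) for p in params}
            try:
                out = model.with_parameters(draws).run(traces)
            except (ValueError, UnknownParameterError):
                if attempt == _MAX_REDRAWS - 1:
                    raise
                continue
            break
        dc[i] = out.incremental.delta_cost
        dq[i] = out.incremental.delta_qaly
    return PSAOutput(dc, dq, n, seed)


def ceac_curve(
    psa: PSAOutput, wtp_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Probability the intervention is cost-effective at each WTP value."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA output")
    out = []
    for w in wtp_grid:
        frac = float(np.mean(w * psa.delta_qaly - psa.delta_cost > 0))
        out.append((float(w), frac))
    return out


# -- default uncertain-parameter set -----------------------------------------


def default_parameter_specs(model: DecisionModel) -> list[ParameterSpec]:
    """Every base-case input carrying a +-20% range: unit costs, AE
    risks/costs/disutilities, state utilities and subsequent-therapy mix
    probabilities.  Survival parameters are excluded (held fixed)."""
    specs: list[ParameterSpec] = []
    for comp in (
        "cisplatin",
        "carboplatin",
        "pemetrexed",
        "nivolumab",
        "ipilimumab",
        "laboratory_test",
        "follow_up",
        "administration",
        "best_supportive_care",
        "pembrolizumab",
        "vinorelbine",
    ):
        specs.append(
            ParameterSpec(f"cost.{comp}", model.costs.unit(comp), psa_family="gamma")
        )
    specs.append(ParameterSpec("utility.pfs", model.utilities.u_pfs, psa_family="beta"))
    specs.append(ParameterSpec("utility.pd", model.utilities.u_pd, psa_family="beta"))
    for arm_token, arm in (
        ("intervention", model.intervention),
        ("comparator", model.comparator),
    ):
        for ae in arm.ae_profile:
            base = f"ae.{arm_token}.{ae.name}"
            specs.append(ParameterSpec(f"{base}.risk", ae.risk, psa_family="beta"))
            specs.append(ParameterSpec(f"{base}.cost", ae.cost, psa_family="gamma"))
            specs.append(
                ParameterSpec(f"{base}.disutility", ae.disutility, psa_family="beta")
            )
        if arm.subsequent is not None:
            specs.append(
                ParameterSpec(
                    f"subsequent.{arm_token}.immunotherapy",
                    arm.subsequent.p_immunotherapy,
                    psa_family="beta",
                )
            )
            specs.append(
                ParameterSpec(
                    f"subsequent.{arm_token}.chemotherapy",
                    arm.subsequent.p_chemotherapy,
                    psa_family="beta",
                )
            )
    return specs
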