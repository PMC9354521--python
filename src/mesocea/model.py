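"""The assembled decision model: two strategy arms plus shared inputs, with
named-parameter overrides used by the sensitivity analyses.

``base_case()`` returns the shipped base case: nivolumab (3 mg/kg q2w) plus
ipilimumab (1 mg/kg q6w) versus platinum-pemetrexed chemotherapy in
unresectable malignant pleural mesothelioma, with the fitted survival laws,
price list, utilities, adverse-event profiles and subsequent-therapy mixes of
the published analysis this package re-implements.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

from .cea import IncrementalResult, WTPContext, incremental, price_threshold_search
from .cohort import CohortTrace, ModelSettings, run_trace
from .errors import UnknownParameterError
from .survival import Family, ParametricDistribution
from .valuation import (
    AdverseEvent,
    ArmResult,
    CostInputs,
    StrategySpec,
    SubsequentTherapyMix,
    UtilityInputs,
    accumulate,
)

# Fitted extrapolation laws (time in months)
NIVO_IPI_OS = ParametricDistribution(Family.WEIBULL, 1.19536, 25.48855)
NIVO_IPI_PFS = ParametricDistribution(Family.LOGNORMAL, 1.88660, 1.23141)
CHEMO_OS = ParametricDistribution(Family.LOGLOGISTIC, 1.7027, 14.1088)
CHEMO_PFS = ParametricDistribution(Family.LOGLOGISTIC, 2.185, 7.392)


@dataclass
class CEAOutcome:
    intervention: ArmResult
    comparator: ArmResult
    incremental: IncrementalResult


@dataclass
class DecisionModel:
    """Both arms plus shared inputs; the unit of work for every analysis."""

    intervention: StrategySpec
    comparator: StrategySpec
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    settings: ModelSettings = field(default_factory=ModelSettings)
    wtp: WTPContext = field(default_factory=WTPContext)

    # -- running -----------------------------------------------------------

    def traces(self) -> dict[str, CohortTrace]:
        """One cohort trace per arm (survival laws are arm properties)."""
        return {
            arm.name: run_trace(arm.os_dist, arm.pfs_dist, self.settings)
            for arm in (self.intervention, self.comparator)
        }

    def run(self, traces: dict[str, CohortTrace] | None = None) -> CEAOutcome:
        """Value both arms and compare them.

        ``traces`` may carry precomputed cohort traces (the sensitivity
        analyses hold survival fixed, so the traces never change there).
        """
        if traces is None:
            traces = self.traces()
        iv = accumulate(
            traces[self.intervention.name],
            self.intervention,
            self.costs,
            self.utilities,
            self.settings,
        )
        cp = accumulate(
            traces[self.comparator.name],
            self.comparator,
            self.costs,
            self.utilities,
            self.settings,
        )
        return CEAOutcome(iv, cp, incremental(iv, cp))

    # -- named-parameter overrides ----------------------------------------

    def with_parameters(self, overrides: dict[str, float]) -> "DecisionModel":
        """Deep copy with named inputs replaced (see ``parameter names``).

        Names:
          ``cost.<component>``                         unit cost
          ``utility.pfs`` / ``utility.pd``             state utilities
          ``ae.<arm>.<event>.risk|cost|disutility``    adverse-event fields
          ``subsequent.<arm>.immunotherapy|chemotherapy``  mix probabilities
        ``<arm>`` is ``intervention`` or ``comparator``.
        """
        m = copy.deepcopy(self)
        for name, value in overrides.items():
            m._set_parameter(name, float(value))
        return m

    def _arm(self, token: str) -> StrategySpec:
        if token == "intervention":
            return self.intervention
        if token == "comparator":
            return self.comparator
        raise UnknownParameterError(f"unknown arm {token!r}")

    def _set_parameter(self, name: str, value: float) -> None:
        parts = name.split(".")
        try:
            if parts[0] == "cost" and len(parts) == 2:
                if not hasattr(self.costs, parts[1]):
                    raise UnknownParameterError(name)
                setattr(self.costs, parts[1], value)
            elif parts[0] == "utility" and len(parts) == 2:
                setattr(self.utilities, {"pfs": "u_pfs", "pd": "u_pd"}[parts[1]], value)
            elif parts[0] == "ae" and len(parts) == 4:
                arm = self._arm(parts[1])
                for ae in arm.ae_profile:
                    if ae.name == parts[2]:
                        if parts[3] not in ("risk", "cost", "disutility"):
                            raise UnknownParameterError(name)
                        setattr(ae, parts[3], value)
                        break
                else:
                    raise UnknownParameterError(name)
            elif parts[0] == "subsequent" and len(parts) == 3:
                arm = self._arm(parts[1])
                attr = {
                    "immunotherapy": "p_immunotherapy",
                    "chemotherapy": "p_chemotherapy",
                }[parts[2]]
                setattr(arm.subsequent, attr, value)
            else:
                raise UnknownParameterError(name)
        except KeyError:
            raise UnknownParameterError(name) from None

    # -- price-threshold convenience ---------------------------------------

    def icer_at_drug_reduction(
        self,
        r: float,
        reducible: tuple[str, ...] = ("nivolumab", "ipilimumab"),
        traces: dict[str, CohortTrace] | None = None,
    ) -> float:
        """ICER per QALY with the reducible drug prices cut by fraction r."""
        overrides = {
            f"cost.{c}": (1.0 - r) * self.costs.unit(c) for c in reducible
        }
        return self.with_parameters(overrides).run(traces).incremental.icer_per_qaly

    def find_price_threshold(
        self, reducible: tuple[str, ...] = ("nivolumab", "ipilimumab")
    ) -> tuple[float, float]:
        """Smallest drug-price reduction making the intervention cost-effective."""
        traces = self.traces()
        return price_threshold_search(
            lambda r: self.icer_at_drug_reduction(r, reducible, traces), self.wtp
        )


def nivo_ipi_strategy() -> StrategySpec:
    """Intervention arm: treat-to-progression immunotherapy."""
    return StrategySpec(
        name="nivolumab_ipilimumab",
        os_dist=NIVO_IPI_OS,
        pfs_dist=NIVO_IPI_PFS,
        on_treatment={"nivolumab": 1.0, "ipilimumab": 1.0},
        ae_profile=[
            AdverseEvent("diarrhea", 0.003, 303.0, -0.047),
            AdverseEvent("increased_lipase", 0.005, 2933.0, -0.47),
            AdverseEvent("increased_amylase", 0.003, 2933.0, -0.47),
        ],
        subsequent=SubsequentTherapyMix(0.033, 0.432),
        max_treatment_cycles=None,
    )


def chemotherapy_strategy() -> StrategySpec:
    """Comparator arm: platinum (50/50 cisplatin/carboplatin) plus
    pemetrexed, capped at 6 cycles."""
    return StrategySpec(
        name="chemotherapy",
        os_dist=CHEMO_OS,
        pfs_dist=CHEMO_PFS,
        on_treatment={"pemetrexed": 1.0, "cisplatin": 0.5, "carboplatin": 0.5},
        ae_profile=[
            AdverseEvent("anemia", 0.36, 493.04, -0.09),
            AdverseEvent("nausea", 0.36, 218.27, -0.048),
            AdverseEvent("decreased_appetite", 0.18, 115.4, -0.038),
        ],
        subsequent=SubsequentTherapyMix(0.202, 0.315),
        max_treatment_cycles=6,
    )


def base_case(settings: ModelSettings | None = None) -> DecisionModel:
    """The shipped base case with all default inputs."""
    return DecisionModel(
        intervention=nivo_ipi_strategy(),
        comparator=chemotherapy_strategy(),
        settings=settings or ModelSettings(),
    )
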