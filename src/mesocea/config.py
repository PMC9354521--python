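"""YAML configuration: a machine-readable twin of the base-case input table.

The shipped default file (``mesocea/data/default_config.yaml``) reproduces
every base-case input verbatim; loading it and running ``base-case`` is the
reference pipeline.  Validation is schema-strict: unknown keys are rejected
and every nested type invariant (utility bounds, probability bounds,
positivity) is enforced at load with a message naming the offending key.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cea import WTPContext
from .cohort import ModelSettings
from .errors import ConfigError
from .model import DecisionModel
from .survival import ParametricDistribution
from .valuation import (
    AdverseEvent,
    CostInputs,
    StrategySpec,
    SubsequentTherapyMix,
    UtilityInputs,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class UnitsCfg(_Strict):
    time: Literal["months"] = "months"
    currency: Literal["USD-2021"] = "USD-2021"


class SettingsCfg(_Strict):
    cycle_days: float = Field(21.0, gt=0)
    horizon_years: float = Field(10.0, gt=0)
    annual_discount: float = Field(0.03, ge=0, lt=1)
    half_cycle: bool = True
    mode: Literal["partitioned", "markov"] = "partitioned"
    annual_step_discount: bool = False


class WTPCfg(_Strict):
    per_qaly: float = Field(207659.0, gt=0)


class DistributionCfg(_Strict):
    family: Literal["weibull", "lognormal", "loglogistic"]
    parameters: list[float] = Field(min_length=2, max_length=2)


class CostsCfg(_Strict):
    cisplatin: float = Field(ge=0)
    carboplatin: float = Field(ge=0)
    pemetrexed: float = Field(ge=0)
    nivolumab: float = Field(ge=0)
    ipilimumab: float = Field(ge=0)
    laboratory_test: float = Field(ge=0)
    follow_up: float = Field(ge=0)
    administration: float = Field(ge=0)
    best_supportive_care: float = Field(ge=0)
    pembrolizumab: float = Field(ge=0)
    vinorelbine: float = Field(ge=0)
    body_surface_area: float = Field(1.68, gt=0)


class UtilitiesCfg(_Strict):
    pfs: float = Field(ge=0, le=1)
    pd: float = Field(ge=0, le=1)


class AdverseEventCfg(_Strict):
    name: str
    risk: float = Field(ge=0, le=1)
    cost: float = Field(ge=0)
    disutility: float = Field(le=0)


class SubsequentCfg(_Strict):
    immunotherapy: float = Field(ge=0, le=1)
    chemotherapy: float = Field(ge=0, le=1)
    immunotherapy_drug: str = "pembrolizumab"
    chemotherapy_drug: str = "vinorelbine"
    duration_cycles: int = Field(6, ge=0)


class StrategyCfg(_Strict):
    name: str
    os: DistributionCfg
    pfs: DistributionCfg
    on_treatment: dict[str, float]
    max_treatment_cycles: int | None = None
    adverse_events: list[AdverseEventCfg] = []
    subsequent: SubsequentCfg


class StrategiesCfg(_Strict):
    intervention: StrategyCfg
    comparator: StrategyCfg


class AnalysisConfig(_Strict):
    """Validated top-level configuration."""

    units: UnitsCfg = UnitsCfg()
    settings: SettingsCfg = SettingsCfg()
    wtp: WTPCfg = WTPCfg()
    costs: CostsCfg
    utilities: UtilitiesCfg
    strategies: StrategiesCfg

    def to_model(self) -> DecisionModel:
        def dist(d: DistributionCfg) -> ParametricDistribution:
            return ParametricDistribution.from_dict(d.model_dump())

        def strategy(s: StrategyCfg) -> StrategySpec:
            return StrategySpec(
                name=s.name,
                os_dist=dist(s.os),
                pfs_dist=dist(s.pfs),
                on_treatment=dict(s.on_treatment),
                ae_profile=[
                    AdverseEvent(a.name, a.risk, a.cost, a.disutility)
                    for a in s.adverse_events
                ],
                subsequent=SubsequentTherapyMix(
                    s.subsequent.immunotherapy,
                    s.subsequent.chemotherapy,
                    s.subsequent.immunotherapy_drug,
                    s.subsequent.chemotherapy_drug,
                    s.subsequent.duration_cycles,
                ),
                max_treatment_cycles=s.max_treatment_cycles,
            )

        costs = CostInputs(**self.costs.model_dump())
        return DecisionModel(
            intervention=strategy(self.strategies.intervention),
            comparator=strategy(self.strategies.comparator),
            costs=costs,
            utilities=UtilityInputs(self.utilities.pfs, self.utilities.pd),
            settings=ModelSettings(**self.settings.model_dump()),
            wtp=WTPContext(self.wtp.per_qaly),
        )


def default_config_path() -> Path:
    return Path(resources.files("mesocea") / "data" / "default_config.yaml")


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load and validate a YAML config (the shipped default when ``path`` is
    None); raises :class:`ConfigError` naming the offending key."""
    p = Path(path) if path is not None else default_config_path()
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    try:
        return AnalysisConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc
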