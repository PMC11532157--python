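"""Per-cycle and total discounted costs per strategy arm.

Cost items: drug acquisition under dosing rules (flat, per-kg, per-m2 body
surface area, Calvert AUC), serious-adverse-event management, routine
monitoring, second-line (subsequent) therapy and best supportive care after
progression.  All monetary amounts are USD; per-cycle costs are charged at
cycle start to the patients occupying the relevant state at that time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

import numpy as np

from .psm_engine import ModelConfig, StateTrace
from .survival import ParametricSurvival

SAE_EVENTS = ("anaemia", "neutropenia", "diarrhoea", "hypertension")


@dataclass
class PatientProfile:
    """Reference patient used for body-size dosing."""

    body_surface_area_m2: float = 1.64
    weight_kg: float = 60.0
    creatinine_clearance_ml_min: float = 70.0

    def validate(self) -> list:
        return [
            f"{f.name} must be > 0, got {getattr(self, f.name)}"
            for f in fields(self)
            if getattr(self, f.name) <= 0
        ]


class DoseKind(enum.Enum):
    FLAT_MG = "flat_mg"
    PER_KG = "per_kg"
    PER_M2 = "per_m2"
    CALVERT_AUC = "calvert_auc"


@dataclass(frozen=True)
class DoseRule:
    kind: DoseKind
    amount: float  # mg, mg/kg, mg/m2 or AUC target

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


def dose_mg(rule: DoseRule, profile: PatientProfile) -> float:
    """Administered dose in mg.

    Calvert formula for carboplatin: dose = AUC * (GFR + 25), with creatinine
    clearance standing in for GFR.
    """
    if rule.kind is DoseKind.FLAT_MG:
        return rule.amount
    if rule.kind is DoseKind.PER_KG:
        return rule.amount * profile.weight_kg
    if rule.kind is DoseKind.PER_M2:
        return rule.amount * profile.body_surface_area_m2
    if rule.kind is DoseKind.CALVERT_AUC:
        return rule.amount * (profile.creatinine_clearance_ml_min + 25.0)
    raise ValueError(f"unknown dose rule kind {rule.kind!r}")


@dataclass
class CostInputs:
    """Unit prices and event/management costs (USD)."""

    # per-mg drug prices
    price_atezolizumab: float = 3.88
    price_bevacizumab: float = 1.60
    price_paclitaxel: float = 0.24
    price_cisplatin: float = 0.22
    price_carboplatin: float = 0.086
    # SAE (grade >= 3) management, per occurrence-cycle
    sae_anaemia: float = 531.70
    sae_neutropenia: float = 461.50
    sae_diarrhoea: float = 88.38
    sae_hypertension: float = 12.90
    # other per-cycle items
    subsequent_treatment: float = 137.61
    best_supportive_care: float = 337.50
    follow_up: float = 55.6
    laboratory: float = 92.50
    ct_scan: float = 105.90

    def validate(self) -> list:
        return [
            f"{f.name} must be >= 0, got {getattr(self, f.name)}"
            for f in fields(self)
            if getattr(self, f.name) < 0
        ]

    def sae_cost(self, event: str) -> float:
        return getattr(self, f"sae_{event}")

    @property
    def monitoring_per_cycle(self) -> float:
        return self.follow_up + self.laboratory + self.ct_scan

    def scaled(self, factor: float) -> "CostInputs":
        """All unit costs multiplied by ``factor`` (currency re-scaling)."""
        return CostInputs(**{f.name: getattr(self, f.name) * factor for f in fields(self)})


class Schedule(enum.Enum):
    INDUCTION = "induction"      # first `induction_cycles` cycles only
    MAINTENANCE = "maintenance"  # while progression-free (optionally capped)


@dataclass(frozen=True)
class DrugComponent:
    """One drug of a regimen: price source, dose rule, schedule, mix weight."""

    name: str
    price_attr: str  # attribute of CostInputs
    dose_rule: DoseRule
    schedule: Schedule
    weight: float = 1.0  # e.g. platinum mix fraction


@dataclass
class SAEProfile:
    """Grade >= 3 serious-adverse-event incidences for one arm."""

    anaemia: float
    neutropenia: float
    diarrhoea: float
    hypertension: float

    def incidence(self, event: str) -> float:
        return getattr(self, event)

    def validate(self) -> list:
        return [
            f"SAE incidence {f.name} must be in [0, 1], got {getattr(self, f.name)}"
            for f in fields(self)
            if not 0 <= getattr(self, f.name) <= 1
        ]


@dataclass
class StrategyArm:
    """A treatment strategy: regimen, SAE profile, downstream care, curves."""

    name: str
    components: list
    sae: SAEProfile
    subsequent_therapy_proportion: float
    response_cap_months: float  # median duration of response
    pfs: ParametricSurvival
    os: ParametricSurvival

    def validate(self) -> list:
        bad = self.sae.validate()
        if not 0 <= self.subsequent_therapy_proportion <= 1:
            bad.append(
                "subsequent_therapy_proportion must be in [0, 1], "
                f"got {self.subsequent_therapy_proportion}"
            )
        if self.response_cap_months <= 0:
            bad.append(f"response_cap_months must be > 0, got {self.response_cap_months}")
        return bad

    def expected_sae_cost(self, costs: CostInputs) -> float:
        return sum(self.sae.incidence(e) * costs.sae_cost(e) for e in SAE_EVENTS)


def _platinum_weight(component: DrugComponent, config: ModelConfig) -> float:
    frac = config.platinum_mix_cisplatin_fraction
    if component.name == "cisplatin":
        return frac
    if component.name == "carboplatin":
        return 1.0 - frac
    return component.weight


def cycle_drug_cost(arm: StrategyArm, profile: PatientProfile,
                    config: ModelConfig, cycle_index: int,
                    costs: CostInputs) -> float:
    """Acquisition cost of the drugs administered at the start of one cycle."""
    if not 0 <= cycle_index < config.n_cycles:
        raise ValueError(f"cycle_index {cycle_index} outside horizon")
    t = cycle_index * config.cycle_length_months
    total = 0.0
    for comp in arm.components:
        if comp.schedule is Schedule.INDUCTION:
            if cycle_index >= config.induction_cycles:
                continue
        elif config.treatment_duration == "response_cap" and t >= arm.response_cap_months:
            continue
        total += (
            _platinum_weight(comp, config)
            * dose_mg(comp.dose_rule, profile)
            * getattr(costs, comp.price_attr)
        )
    return total


@dataclass
class CostBreakdown:
    """Itemized discounted totals (USD); items sum exactly to ``total``."""

    drug: float
    sae: float
    monitoring: float
    subsequent_therapy: float
    supportive_care: float

    @property
    def total(self) -> float:
        return (self.drug + self.sae + self.monitoring
                + self.subsequent_therapy + self.supportive_care)

    def as_dict(self) -> dict:
        return {
            "drug": self.drug,
            "sae": self.sae,
            "monitoring": self.monitoring,
            "subsequent_therapy": self.subsequent_therapy,
            "supportive_care": self.supportive_care,
            "total": self.total,
        }


def on_treatment_weight(arm: StrategyArm, trace: StateTrace,
                        config: ModelConfig) -> np.ndarray:
    """Discounted PF occupancy at the start of each on-treatment cycle."""
    t = trace.time_months[:-1]
    w = trace.pf_start * trace.disc_start
    if config.treatment_duration == "response_cap":
        w = w * (t < arm.response_cap_months)
    return w


def total_discounted_cost(arm: StrategyArm, trace: StateTrace,
                          costs: CostInputs, config: ModelConfig,
                          profile: PatientProfile) -> CostBreakdown:
    """Itemized discounted cost of one arm over the model horizon.

    - drug: per-cycle regimen cost applied to PF occupancy per schedule
      (induction drugs for the first six cycles; maintenance drugs until
      progression, by default capped at the arm's median duration of
      response);
    - sae: expected management cost (sum of incidence x unit cost), charged
      per on-treatment cycle by default, or once at model entry;
    - monitoring: follow-up + laboratory + CT, by default every alive cycle;
    - subsequent_therapy: second-line cost per progressed cycle times the
      arm's subsequent-therapy proportion;
    - supportive_care: best supportive care per progressed cycle (by default
      for all progressed occupancy; optionally only the complement of the
      subsequent-therapy proportion).
    """
    if trace.label and trace.label != arm.name:
        raise ValueError(f"trace built for {trace.label!r}, not {arm.name!r}")
    config.require_valid()
    bad = arm.validate() + costs.validate() + profile.validate()
    if bad:
        raise ValueError("; ".join(bad))

    t_start = trace.time_months[:-1]
    w_tx = on_treatment_weight(arm, trace, config)

    drug = 0.0
    for comp in arm.components:
        per_admin = (
            _platinum_weight(comp, config)
            * dose_mg(comp.dose_rule, profile)
            * getattr(costs, comp.price_attr)
        )
        if comp.schedule is Schedule.INDUCTION:
            w = trace.pf_start * trace.disc_start
            drug += per_admin * float(np.sum(w[: config.induction_cycles]))
        else:
            drug += per_admin * float(np.sum(w_tx))

    sae_exp = arm.expected_sae_cost(costs)
    if config.sae_timing == "per_cycle":
        sae = sae_exp * float(np.sum(w_tx))
    else:  # once, at model entry (everyone progression-free, undiscounted)
        sae = sae_exp

    if config.monitoring_scope == "alive":
        monitoring = costs.monitoring_per_cycle * float(
            np.sum(trace.alive_start * trace.disc_start)
        )
    else:  # labs + CT while on treatment, follow-up also in PD
        monitoring = (costs.laboratory + costs.ct_scan) * float(np.sum(w_tx))
        monitoring += costs.follow_up * float(
            np.sum((trace.pf_start + trace.pd_start) * trace.disc_start)
        )

    w_pd = float(np.sum(trace.pd_start * trace.disc_start))
    prop = arm.subsequent_therapy_proportion
    subsequent = costs.subsequent_treatment * prop * w_pd
    if config.bsc_scope == "all_pd":
        supportive = costs.best_supportive_care * w_pd
    else:
        supportive = costs.best_supportive_care * (1.0 - prop) * w_pd

    return CostBreakdown(
        drug=drug,
        sae=sae,
        monitoring=monitoring,
        subsequent_therapy=subsequent,
        supportive_care=supportive,
    )
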