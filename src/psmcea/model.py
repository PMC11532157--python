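"""Full model input container and the end-to-end evaluation pipeline."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .cea import ArmTotals, CEAResult, incremental_analysis
from .cost_model import (CostBreakdown, CostInputs, PatientProfile,
                         StrategyArm, total_discounted_cost)
from .psm_engine import ModelConfig, StateTrace, build_trace
from .qaly_model import UtilityInputs, total_discounted_qaly


@dataclass
class Inputs:
    """Everything a model run needs: arms, prices, utilities, patient, config."""

    config: ModelConfig
    profile: PatientProfile
    costs: CostInputs
    utilities: UtilityInputs
    intervention: StrategyArm
    control: StrategyArm

    def copy(self) -> "Inputs":
        return copy.deepcopy(self)

    def validate(self) -> list:
        bad = self.config.validate()
        bad += self.profile.validate()
        bad += self.costs.validate()
        bad += self.utilities.validate()
        for arm in (self.intervention, self.control):
            bad += [f"{arm.name}: {msg}" for msg in arm.validate()]
        return bad


@dataclass
class ArmOutcome:
    """One arm's trace, itemized costs and QALY total."""

    arm: StrategyArm
    trace: StateTrace
    costs: CostBreakdown
    qaly: float

    @property
    def totals(self) -> ArmTotals:
        return ArmTotals(name=self.arm.name, cost=self.costs.total, qaly=self.qaly)


def evaluate_arm(arm: StrategyArm, inputs: Inputs) -> ArmOutcome:
    trace = build_trace(arm.pfs, arm.os, inputs.config, label=arm.name)
    breakdown = total_discounted_cost(
        arm, trace, inputs.costs, inputs.config, inputs.profile
    )
    qaly = total_discounted_qaly(arm, trace, inputs.utilities, inputs.config)
    return ArmOutcome(arm=arm, trace=trace, costs=breakdown, qaly=qaly)


def evaluate(inputs: Inputs) -> CEAResult:
    """Run both arms through the partitioned survival pipeline and pair them."""
    bad = inputs.validate()
    if bad:
        raise ValueError("; ".join(bad))
    ref = evaluate_arm(inputs.control, inputs)
    comp = evaluate_arm(inputs.intervention, inputs)
    return incremental_analysis(
        ref.totals, comp.totals, wtp=inputs.config.wtp_per_qaly
    )


def evaluate_detailed(inputs: Inputs) -> tuple:
    """(CEAResult, intervention ArmOutcome, control ArmOutcome)."""
    bad = inputs.validate()
    if bad:
        raise ValueError("; ".join(bad))
    ref = evaluate_arm(inputs.control, inputs)
    comp = evaluate_arm(inputs.intervention, inputs)
    res = incremental_analysis(ref.totals, comp.totals, wtp=inputs.config.wtp_per_qaly)
    return res, comp, ref
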