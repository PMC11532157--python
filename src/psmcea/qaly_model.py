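"""Quality-adjusted life-year accrual from a state trace.

Two accrual conventions are implemented (see docs/methods.md):

``alive_weighted`` (default, reproduces the published base case)
    Every alive patient accrues the progressive-disease utility u_PD and
    progression-free patients accrue u_PF *on top*; QALYs are not
    discounted (costs remain discounted).  The effective progression-free
    weight u_PF + u_PD exceeds 1 — a non-standard convention retained
    because the published totals are arithmetically consistent only with it.

``partitioned`` (textbook)
    Mutually exclusive states: u_PF on progression-free occupancy, u_PD on
    progressed occupancy, zero for death, discounted per cycle.

Adverse-event disutilities are treated as decrements applied once at model
entry, lasting one cycle per affected patient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .cost_model import SAE_EVENTS, StrategyArm
from .psm_engine import ModelConfig, StateTrace


@dataclass
class UtilityInputs:
    """Health-state utilities and adverse-event disutilities, all in [0, 1]."""

    progression_free: float = 0.85
    progressive: float = 0.52
    dis_anaemia: float = 0.38
    dis_neutropenia: float = 0.20
    dis_diarrhoea: float = 0.11
    dis_hypertension: float = 0.10

    def disutility(self, event: str) -> float:
        return getattr(self, f"dis_{event}")

    def validate(self) -> list:
        return [
            f"{f.name} must be in [0, 1], got {getattr(self, f.name)}"
            for f in fields(self)
            if not 0 <= getattr(self, f.name) <= 1
        ]


def ae_decrement(arm: StrategyArm, utilities: UtilityInputs,
                 config: ModelConfig) -> float:
    """Expected one-off QALY loss from grade >= 3 adverse events."""
    burden = sum(
        arm.sae.incidence(e) * utilities.disutility(e) for e in SAE_EVENTS
    )
    return burden * config.cycle_length_years


def total_discounted_qaly(arm: StrategyArm, trace: StateTrace,
                          utilities: UtilityInputs, config: ModelConfig) -> float:
    """QALY total for one arm under the configured accrual convention."""
    if trace.label and trace.label != arm.name:
        raise ValueError(f"trace built for {trace.label!r}, not {arm.name!r}")
    bad = utilities.validate()
    if bad:
        raise ValueError("; ".join(bad))
    config.require_valid()

    w = trace.disc_mid if config.discount_qalys else np.ones(trace.n_cycles)
    if config.qaly_accrual == "alive_weighted":
        per_cycle = (
            trace.pf_mid * utilities.progression_free
            + trace.alive_mid * utilities.progressive
        )
    else:  # partitioned
        per_cycle = (
            trace.pf_mid * utilities.progression_free
            + trace.pd_mid * utilities.progressive
        )
    qaly = float(np.sum(per_cycle * w)) * config.cycle_length_years
    return qaly - ae_decrement(arm, utilities, config)


def life_years(trace: StateTrace, config: ModelConfig,
               discounted: bool = False) -> float:
    """Restricted (optionally discounted) life expectancy over the horizon."""
    w = trace.disc_mid if discounted else np.ones(trace.n_cycles)
    return float(np.sum(trace.alive_mid * w)) * config.cycle_length_years
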