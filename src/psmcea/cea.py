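"""Incremental cost-effectiveness analysis of two strategy arms."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class ArmTotals:
    """Discounted cost and QALY total for one strategy."""

    name: str
    cost: float
    qaly: float


@dataclass
class CEAResult:
    """Pairwise incremental analysis at a willingness-to-pay threshold.

    ``icer`` is None when the QALY increment is zero (undefined) or when one
    arm dominates (cheaper and more effective); ``nmb`` is always computed.
    """

    reference: ArmTotals
    comparator: ArmTotals
    wtp: float

    @property
    def incremental_cost(self) -> float:
        return self.comparator.cost - self.reference.cost

    @property
    def incremental_qaly(self) -> float:
        return self.comparator.qaly - self.reference.qaly

    @property
    def dominance(self) -> str:
        dc, de = self.incremental_cost, self.incremental_qaly
        if dc < 0 and de > 0:
            return "comparator_dominant"
        if dc > 0 and de < 0:
            return "reference_dominant"
        return "none"

    @property
    def icer(self):
        if self.dominance != "none" or self.incremental_qaly == 0:
            return None
        return self.incremental_cost / self.incremental_qaly

    @property
    def nmb(self) -> float:
        """Net monetary benefit of the comparator at the given threshold."""
        return self.wtp * self.incremental_qaly - self.incremental_cost

    @property
    def cost_effective(self) -> bool:
        if self.dominance == "comparator_dominant":
            return True
        if self.dominance == "reference_dominant":
            return False
        icer = self.icer
        return icer is not None and self.incremental_qaly > 0 and icer <= self.wtp

    def as_dict(self) -> dict:
        icer = self.icer
        return {
            "reference": {"name": self.reference.name,
                          "cost": self.reference.cost, "qaly": self.reference.qaly},
            "comparator": {"name": self.comparator.name,
                           "cost": self.comparator.cost, "qaly": self.comparator.qaly},
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "icer": None if icer is None or not math.isfinite(icer) else icer,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "dominance": self.dominance,
            "cost_effective": self.cost_effective,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> pd.DataFrame:
        """Base-case summary shaped like a standard two-arm results table."""
        icer = self.icer
        return pd.DataFrame(
            {
                self.comparator.name: [
                    self.comparator.cost, self.comparator.qaly,
                    self.incremental_cost, self.incremental_qaly,
                    icer if icer is not None else float("nan"),
                ],
                self.reference.name: [
                    self.reference.cost, self.reference.qaly,
                    float("nan"), float("nan"), float("nan"),
                ],
            },
            index=["cost_usd", "qaly", "incremental_cost_usd",
                   "incremental_qaly", "icer_usd_per_qaly"],
        )


def incremental_analysis(reference: ArmTotals, comparator: ArmTotals,
                         wtp: float) -> CEAResult:
    """Pair two arm totals into increments, ICER and net monetary benefit."""
    return CEAResult(reference=reference, comparator=comparator, wtp=wtp)
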