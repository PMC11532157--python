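"""Fixture generation: pseudo individual-patient data, digitized curves, and
the packaged base-case configuration.

Everything the pipeline consumes can be produced here without any external
download: survival records drawn from the published log-logistic curves with
administrative censoring, synthetic digitized Kaplan-Meier coordinate files
(stand-ins for graph-digitizer output), and the complete published input
table as a validated, YAML-round-trippable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, optimize

from .cost_model import (CostInputs, DoseKind, DoseRule, DrugComponent,
                         PatientProfile, SAEProfile, Schedule, StrategyArm)
from .model import Inputs
from .psm_engine import ModelConfig
from .qaly_model import UtilityInputs
from .survival import Family, ParametricSurvival, PseudoIPD


@dataclass(frozen=True)
class FixtureSpec:
    """Generating parameters for one pseudo-IPD fixture."""

    gamma: float
    lam: float
    n: int
    censoring_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError(
                f"censoring_fraction must be in [0, 1), got {self.censoring_fraction}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def model(self) -> ParametricSurvival:
        return ParametricSurvival(Family.LOGLOGISTIC, (self.gamma, self.lam))


def _censoring_horizon(model: ParametricSurvival, fraction: float) -> float:
    """Upper end c of Uniform(0, c) censoring giving the requested fraction.

    A record is censored when C < T; with C ~ Uniform(0, c) that probability
    is (1/c) * integral_0^c S(t) dt, solved for c numerically.
    """
    def censored_prob(c):
        val, _ = integrate.quad(model.survival, 0.0, c, limit=200)
        return val / c

    med = model.median()
    lo, hi = med * 1e-3, med * 1e3
    if censored_prob(hi) > fraction:
        raise ValueError(f"censoring fraction {fraction} unreachable")
    return optimize.brentq(lambda c: censored_prob(c) - fraction, lo, hi)


def simulate_ipd(spec: FixtureSpec) -> PseudoIPD:
    """Draw right-censored log-logistic survival records.

    Event times use the inverse CDF t = ((1/u - 1)/lam)**(1/gamma) with
    u ~ Uniform(0, 1); censoring times are independent Uniform(0, c) with c
    calibrated so the expected censored share equals ``censoring_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    t = ((1.0 / u - 1.0) / spec.lam) ** (1.0 / spec.gamma)
    if spec.censoring_fraction == 0:
        return PseudoIPD(t, np.ones(spec.n, dtype=int))
    c = rng.uniform(0.0, _censoring_horizon(spec.model, spec.censoring_fraction),
                    size=spec.n)
    events = (t <= c).astype(int)
    return PseudoIPD(np.minimum(t, c), events)


def emit_digitized_curve(model: ParametricSurvival, grid, noise_sd: float = 0.0,
                         seed: int = 0, path=None) -> pd.DataFrame:
    """Synthetic digitized survival-curve coordinates (time, probability).

    Gaussian digitization noise is added to the closed-form S(t) and clamped
    to [0, 1].  When ``path`` is given the table is written as a two-column
    CSV with a header row and the seed recorded in a leading comment.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s = np.atleast_1d(model.survival(grid))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = np.clip(s + rng.normal(0.0, noise_sd, size=s.shape), 0.0, 1.0)
    df = pd.DataFrame({"time_months": grid, "survival_probability": s})
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# seed={seed} noise_sd={noise_sd}\n")
            df.to_csv(fh, index=False)
    return df


# -- the published base case ------------------------------------------------

#: log-logistic (shape gamma, rate lambda) per arm and endpoint, months
BASE_CURVES = {
    ("intervention", "pfs"): (1.74, 0.0079),
    ("intervention", "os"): (2.02, 0.00099),
    ("control", "pfs"): (2.18, 0.0052),
    ("control", "os"): (2.16, 0.0011),
}

#: trial medians (months) the fitted curves should bracket: PFS, OS per arm
TRIAL_MEDIANS = {
    ("intervention", "pfs"): 13.7,
    ("intervention", "os"): 32.1,
    ("control", "pfs"): 10.4,
    ("control", "os"): 22.8,
}


def _curve(arm: str, endpoint: str) -> ParametricSurvival:
    return ParametricSurvival(Family.LOGLOGISTIC, BASE_CURVES[(arm, endpoint)])


def _chemo_backbone() -> list:
    return [
        DrugComponent("bevacizumab", "price_bevacizumab",
                      DoseRule(DoseKind.PER_KG, 15.0), Schedule.MAINTENANCE),
        DrugComponent("paclitaxel", "price_paclitaxel",
                      DoseRule(DoseKind.PER_M2, 175.0), Schedule.INDUCTION),
        DrugComponent("cisplatin", "price_cisplatin",
                      DoseRule(DoseKind.PER_M2, 50.0), Schedule.INDUCTION),
        DrugComponent("carboplatin", "price_carboplatin",
                      DoseRule(DoseKind.CALVERT_AUC, 5.0), Schedule.INDUCTION),
    ]


def base_case_config() -> Inputs:
    """The complete published input table as a validated model configuration."""
    intervention = StrategyArm(
        name="atezolizumab",
        components=[
            DrugComponent("atezolizumab", "price_atezolizumab",
                          DoseRule(DoseKind.FLAT_MG, 1200.0), Schedule.MAINTENANCE),
        ] + _chemo_backbone(),
        sae=SAEProfile(anaemia=0.15, neutropenia=0.18,
                       diarrhoea=0.05, hypertension=0.18),
        subsequent_therapy_proportion=0.54,
        response_cap_months=13.6,
        pfs=_curve("intervention", "pfs"),
        os=_curve("intervention", "os"),
    )
    control = StrategyArm(
        name="chemotherapy",
        components=_chemo_backbone(),
        sae=SAEProfile(anaemia=0.08, neutropenia=0.25,
                       diarrhoea=0.03, hypertension=0.16),
        subsequent_therapy_proportion=0.58,
        response_cap_months=8.6,
        pfs=_curve("control", "pfs"),
        os=_curve("control", "os"),
    )
    inputs = Inputs(
        config=ModelConfig(),
        profile=PatientProfile(),
        costs=CostInputs(),
        utilities=UtilityInputs(),
        intervention=intervention,
        control=control,
    )
    bad = inputs.validate()
    if bad:  # pragma: no cover - the packaged table is valid by construction
        raise ValueError("; ".join(bad))
    return inputs


# -- YAML (de)serialization --------------------------------------------------


def _arm_to_dict(arm: StrategyArm) -> dict:
    return {
        "name": arm.name,
        "components": [
            {
                "name": c.name,
                "price_attr": c.price_attr,
                "dose_kind": c.dose_rule.kind.value,
                "dose_amount": c.dose_rule.amount,
                "schedule": c.schedule.value,
                "weight": c.weight,
            }
            for c in arm.components
        ],
        "sae_incidence": {
            "anaemia": arm.sae.anaemia,
            "neutropenia": arm.sae.neutropenia,
            "diarrhoea": arm.sae.diarrhoea,
            "hypertension": arm.sae.hypertension,
        },
        "subsequent_therapy_proportion": arm.subsequent_therapy_proportion,
        "response_cap_months": arm.response_cap_months,
        "pfs": {"family": arm.pfs.family.value, "params": list(arm.pfs.params)},
        "os": {"family": arm.os.family.value, "params": list(arm.os.params)},
    }


def _arm_from_dict(d: dict) -> StrategyArm:
    return StrategyArm(
        name=d["name"],
        components=[
            DrugComponent(
                name=c["name"],
                price_attr=c["price_attr"],
                dose_rule=DoseRule(DoseKind(c["dose_kind"]), c["dose_amount"]),
                schedule=Schedule(c["schedule"]),
                weight=c.get("weight", 1.0),
            )
            for c in d["components"]
        ],
        sae=SAEProfile(**d["sae_incidence"]),
        subsequent_therapy_proportion=d["subsequent_therapy_proportion"],
        response_cap_months=d["response_cap_months"],
        pfs=ParametricSurvival(Family(d["pfs"]["family"]), tuple(d["pfs"]["params"])),
        os=ParametricSurvival(Family(d["os"]["family"]), tuple(d["os"]["params"])),
    )


def inputs_to_dict(inputs: Inputs) -> dict:
    cfg, prof, costs, utils = (inputs.config, inputs.profile,
                               inputs.costs, inputs.utilities)
    return {
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "profile": {k: getattr(prof, k) for k in prof.__dataclass_fields__},
        "costs": {k: getattr(costs, k) for k in costs.__dataclass_fields__},
        "utilities": {k: getattr(utils, k) for k in utils.__dataclass_fields__},
        "intervention": _arm_to_dict(inputs.intervention),
        "control": _arm_to_dict(inputs.control),
    }


def inputs_from_dict(d: dict) -> Inputs:
    known = {"config", "profile", "costs", "utilities", "intervention", "control"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    return Inputs(
        config=ModelConfig(**d["config"]),
        profile=PatientProfile(**d["profile"]),
        costs=CostInputs(**d["costs"]),
        utilities=UtilityInputs(**d["utilities"]),
        intervention=_arm_from_dict(d["intervention"]),
        control=_arm_from_dict(d["control"]),
    )


def inputs_to_yaml(inputs: Inputs, path=None) -> str:
    text = yaml.safe_dump(inputs_to_dict(inputs), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def inputs_from_yaml(path) -> Inputs:
    with open(path) as fh:
        return inputs_from_dict(yaml.safe_load(fh))
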