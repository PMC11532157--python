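"""Registry of model parameters: base values, ranges and PSA distributions.

Each entry addresses one input by a dotted attribute path into
:class:`psmcea.model.Inputs`.  Entries with a published minimum/maximum use
those exact bounds; the remainder default to +/-25% of base.  Survival-curve
parameters carry no ranges and are excluded from both sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Inputs

GAMMA, BETA, BETA_SCALED, FIXED = "gamma", "beta", "beta_scaled", None


@dataclass(frozen=True)
class ParameterSpec:
    """One tunable input: location, uncertainty range and PSA family."""

    name: str
    path: str
    distribution: str | None
    low: float | None = None   # None -> base * 0.75
    high: float | None = None  # None -> base * 1.25
    printed_range: bool = False

    def bounds(self, base: float) -> tuple:
        lo = self.low if self.low is not None else base * 0.75
        hi = self.high if self.high is not None else base * 1.25
        return lo, hi


def get_path(inputs: Inputs, path: str) -> float:
    obj = inputs
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def set_path(inputs: Inputs, path: str, value: float) -> None:
    parts = path.split(".")
    obj = inputs
    for part in parts[:-1]:
        obj = getattr(obj, part)
    setattr(obj, parts[-1], value)


#: Published base-case parameter table (excluding survival rows, below).
TABLE1_PARAMETERS = [
    # drug prices (USD per mg)
    ParameterSpec("price_atezolizumab", "costs.price_atezolizumab", GAMMA, 2.91, 4.85, True),
    ParameterSpec("price_bevacizumab", "costs.price_bevacizumab", GAMMA, 1.20, 2.00, True),
    ParameterSpec("price_paclitaxel", "costs.price_paclitaxel", GAMMA, 0.18, 0.30, True),
    ParameterSpec("price_cisplatin", "costs.price_cisplatin", GAMMA, 0.17, 0.28, True),
    ParameterSpec("price_carboplatin", "costs.price_carboplatin", GAMMA, 0.06, 0.11, True),
    # SAE management costs (USD per cycle)
    ParameterSpec("cost_sae_anaemia", "costs.sae_anaemia", GAMMA, 398.78, 664.63, True),
    ParameterSpec("cost_sae_neutropenia", "costs.sae_neutropenia", GAMMA, 346.13, 576.88, True),
    ParameterSpec("cost_sae_diarrhoea", "costs.sae_diarrhoea", GAMMA, 66.29, 110.48, True),
    ParameterSpec("cost_sae_hypertension", "costs.sae_hypertension", GAMMA, 9.68, 16.13, True),
    # other care costs (USD per cycle)
    ParameterSpec("cost_subsequent_treatment", "costs.subsequent_treatment", GAMMA, 103.21, 172.01, True),
    ParameterSpec("cost_best_supportive_care", "costs.best_supportive_care", GAMMA, 253.13, 421.88, True),
    ParameterSpec("cost_follow_up", "costs.follow_up", GAMMA, 41.70, 69.50, True),
    ParameterSpec("cost_laboratory", "costs.laboratory", GAMMA, 69.38, 115.63, True),
    ParameterSpec("cost_ct_scan", "costs.ct_scan", GAMMA, 79.43, 132.38, True),
    # SAE incidences (no published ranges)
    ParameterSpec("inc_intervention_anaemia", "intervention.sae.anaemia", BETA),
    ParameterSpec("inc_intervention_neutropenia", "intervention.sae.neutropenia", BETA),
    ParameterSpec("inc_intervention_diarrhoea", "intervention.sae.diarrhoea", BETA),
    ParameterSpec("inc_intervention_hypertension", "intervention.sae.hypertension", BETA),
    ParameterSpec("inc_control_anaemia", "control.sae.anaemia", BETA),
    ParameterSpec("inc_control_neutropenia", "control.sae.neutropenia", BETA),
    ParameterSpec("inc_control_diarrhoea", "control.sae.diarrhoea", BETA),
    ParameterSpec("inc_control_hypertension", "control.sae.hypertension", BETA),
    # utilities and disutilities
    ParameterSpec("utility_progression_free", "utilities.progression_free", BETA, 0.64, 1.00, True),
    ParameterSpec("utility_progressive", "utilities.progressive", BETA, 0.39, 0.65, True),
    ParameterSpec("disutility_anaemia", "utilities.dis_anaemia", BETA, 0.29, 0.48, True),
    ParameterSpec("disutility_neutropenia", "utilities.dis_neutropenia", BETA, 0.15, 0.25, True),
    ParameterSpec("disutility_diarrhoea", "utilities.dis_diarrhoea", BETA, 0.08, 0.14, True),
    ParameterSpec("disutility_hypertension", "utilities.dis_hypertension", BETA, 0.08, 0.13, True),
    # patient / global
    ParameterSpec("body_surface_area", "profile.body_surface_area_m2", BETA_SCALED, 1.23, 2.05, True),
    ParameterSpec("discount_rate", "config.discount_rate_annual", BETA_SCALED, 0.04, 0.06, True),
]

#: Structural assumptions additionally explored one-way (not in the PSA).
EXTRA_DSA_PARAMETERS = [
    ParameterSpec("subsequent_proportion_intervention",
                  "intervention.subsequent_therapy_proportion", FIXED),
    ParameterSpec("subsequent_proportion_control",
                  "control.subsequent_therapy_proportion", FIXED),
    ParameterSpec("platinum_cisplatin_fraction",
                  "config.platinum_mix_cisplatin_fraction", FIXED, 0.375, 0.625),
]

#: Survival rows of the published table — fixed in every sensitivity analysis.
SURVIVAL_PARAMETERS = [
    "pfs_intervention_loglogistic",
    "pfs_control_loglogistic",
    "os_intervention_loglogistic",
    "os_control_loglogistic",
]

#: Complete published-table manifest (one name per table row).
TABLE1_MANIFEST = SURVIVAL_PARAMETERS + [p.name for p in TABLE1_PARAMETERS]


def perturbed(inputs: Inputs, path: str, value: float) -> Inputs:
    """A deep copy of ``inputs`` with one parameter replaced."""
    new = inputs.copy()
    set_path(new, path, value)
    return new
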