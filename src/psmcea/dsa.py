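"""Deterministic one-way sensitivity analysis and price-threshold search."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .model import Inputs, evaluate
from .parameters import (EXTRA_DSA_PARAMETERS, TABLE1_PARAMETERS,
                         ParameterSpec, get_path, perturbed)

#: parameters whose domain is the unit interval
_UNIT_INTERVAL = ("utilities.", "sae.", "subsequent_therapy_proportion",
                  "platinum_mix_cisplatin_fraction")


@dataclass
class SensitivityEntry:
    """One tornado bar: ICER at the parameter's low and high value."""

    name: str
    base: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    clamped: bool = False

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer(inputs: Inputs) -> float:
    icer = evaluate(inputs).icer
    return float("nan") if icer is None else icer


def _clamp(path: str, value: float) -> tuple:
    if any(tag in path for tag in _UNIT_INTERVAL):
        clipped = min(max(value, 0.0), 1.0)
        return clipped, clipped != value
    clipped = max(value, 0.0)
    return clipped, clipped != value


def one_way(inputs: Inputs, parameters=None) -> list:
    """Tornado analysis: perturb each parameter alone to its range ends.

    Returns entries sorted by ICER spread, descending (fully deterministic;
    ties keep registry order).  Out-of-domain bounds are clamped and flagged.
    """
    if parameters is None:
        parameters = TABLE1_PARAMETERS + EXTRA_DSA_PARAMETERS
    entries = []
    for spec in parameters:
        base = get_path(inputs, spec.path)
        lo, hi = spec.bounds(base)
        (lo, c1), (hi, c2) = _clamp(spec.path, lo), _clamp(spec.path, hi)
        entries.append(SensitivityEntry(
            name=spec.name, base=base, low=lo, high=hi,
            icer_at_low=_icer(perturbed(inputs, spec.path, lo)),
            icer_at_high=_icer(perturbed(inputs, spec.path, hi)),
            clamped=c1 or c2,
        ))
    entries.sort(key=lambda e: -e.spread)
    return entries


def tornado_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "base": e.base,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "spread": e.spread,
                "clamped": e.clamped,
            }
            for e in entries
        ]
    )


@dataclass
class ThresholdResult:
    """Outcome of the price-reduction threshold search."""

    price_per_mg: float
    icer: float
    reachable: bool
    target_wtp: float


def icer_at_price(inputs: Inputs, price: float,
                  price_attr: str = "price_atezolizumab") -> float:
    return _icer(perturbed(inputs, f"costs.{price_attr}", price))


def price_threshold(inputs: Inputs, target_wtp: float,
                    price_attr: str = "price_atezolizumab",
                    tol: float = 1.0) -> ThresholdResult:
    """Unit price at which the ICER meets a willingness-to-pay threshold.

    Bisects the drug's price on [0, base price] until the ICER is within
    ``tol`` $/QALY of the target.  Monotonicity of the ICER in the price is
    verified numerically first; a target outside the attainable ICER range
    is reported as unreachable (price pinned to the nearer endpoint).
    """
    base_price = get_path(inputs, f"costs.{price_attr}")
    probe = np.linspace(0.0, base_price, 5)
    icers = [icer_at_price(inputs, p, price_attr) for p in probe]
    if np.any(np.diff(icers) < 0):
        raise ValueError(f"ICER is not monotone in {price_attr} on [0, base]")

    f = lambda p: icer_at_price(inputs, p, price_attr) - target_wtp
    f_lo, f_hi = f(0.0), f(base_price)
    if f_lo > 0:
        return ThresholdResult(0.0, f_lo + target_wtp, False, target_wtp)
    if f_hi < 0:
        return ThresholdResult(base_price, f_hi + target_wtp, False, target_wtp)
    price = optimize.brentq(f, 0.0, base_price, xtol=1e-6)
    achieved = icer_at_price(inputs, price, price_attr)
    if abs(achieved - target_wtp) > tol:  # pragma: no cover - brentq is tighter
        raise RuntimeError("threshold search did not converge")
    return ThresholdResult(float(price), float(achieved), True, target_wtp)
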