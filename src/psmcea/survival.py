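"""Parametric survival curves: evaluation, censored maximum likelihood, model selection.

Six families are supported (exponential, Weibull, Gompertz, log-normal,
log-logistic, gamma).  The log-logistic uses the *rate* parameterization

    S(t) = 1 / (1 + lambda * t**gamma)

with shape ``gamma`` and rate-like scale ``lambda`` — the form in which the
base-case curves are published — rather than the scale form
``1 / (1 + (t/alpha)**beta)`` used by lifelines and scipy's ``fisk``.
Conversion helpers between the two forms are provided and tested both ways.

All times are in months.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


class Family(enum.Enum):
    """Candidate distribution families, in deterministic tie-break order."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"
    GAMMA = "gamma"


#: number of free parameters per family
N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.GOMPERTZ: 2,
    Family.LOGNORMAL: 2,
    Family.LOGLOGISTIC: 2,
    Family.GAMMA: 2,
}


class SurvivalDomainError(ValueError):
    """Invalid time or parameter vector for a survival evaluation."""


class NoMedianError(ValueError):
    """S(t) never crosses 0.5 on (0, inf)."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A survival-curve family tag plus its parameter vector (time in months).

    Parameter conventions:

    - exponential: (rate,)                     S(t) = exp(-rate * t)
    - weibull:     (shape, scale)              S(t) = exp(-(t/scale)**shape)
    - gompertz:    (shape a, rate b), a != 0   S(t) = exp(-(b/a) * (exp(a*t) - 1))
    - lognormal:   (mu, sigma)                 S(t) = 1 - Phi((ln t - mu)/sigma)
    - loglogistic: (gamma, lam)                S(t) = 1 / (1 + lam * t**gamma)
    - gamma:       (shape, rate)               S(t) = 1 - P(shape, rate*t)
    """

    family: Family
    params: tuple
    time_unit: str = "months"

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        if p.size != N_PARAMS[self.family]:
            raise SurvivalDomainError(
                f"{self.family.value} expects {N_PARAMS[self.family]} "
                f"parameter(s), got {p.size}"
            )
        if not np.all(np.isfinite(p)):
            raise SurvivalDomainError(f"non-finite params {self.params}")
        positive = {
            Family.EXPONENTIAL: [0],
            Family.WEIBULL: [0, 1],
            Family.GOMPERTZ: [1],  # shape may be negative, rate must be > 0
            Family.LOGNORMAL: [1],
            Family.LOGLOGISTIC: [0, 1],
            Family.GAMMA: [0, 1],
        }[self.family]
        for i in positive:
            if p[i] <= 0:
                raise SurvivalDomainError(
                    f"params[{i}] of {self.family.value} must be > 0, got {p[i]}"
                )

    # -- closed forms ----------------------------------------------------

    def survival(self, t):
        """S(t), vectorized; raises on negative t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise SurvivalDomainError("t must be >= 0")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        f, p = self.family, self.params
        if f is Family.EXPONENTIAL:
            s = np.exp(-p[0] * t)
        elif f is Family.WEIBULL:
            s = np.exp(-((t / p[1]) ** p[0]))
        elif f is Family.GOMPERTZ:
            a, b = p
            s = np.exp(-(b / a) * np.expm1(a * t))
        elif f is Family.LOGNORMAL:
            mu, sig = p
            s = np.ones_like(t)
            pos = t > 0
            s[pos] = special.ndtr(-(np.log(t[pos]) - mu) / sig)
        elif f is Family.LOGLOGISTIC:
            g, lam = p
            s = np.ones_like(t)
            pos = t > 0
            s[pos] = 1.0 / (1.0 + lam * t[pos] ** g)
        else:  # gamma
            shape, rate = p
            s = special.gammaincc(shape, rate * t)
        return float(s[0]) if scalar else s

    def log_density(self, t):
        """log f(t) for t > 0, vectorized."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise SurvivalDomainError("density requires t > 0")
        f, p = self.family, self.params
        if f is Family.EXPONENTIAL:
            return np.log(p[0]) - p[0] * t
        if f is Family.WEIBULL:
            k, s = p
            return np.log(k / s) + (k - 1) * np.log(t / s) - (t / s) ** k
        if f is Family.GOMPERTZ:
            a, b = p
            return np.log(b) + a * t - (b / a) * np.expm1(a * t)
        if f is Family.LOGNORMAL:
            mu, sig = p
            z = (np.log(t) - mu) / sig
            return -np.log(t * sig * np.sqrt(2 * np.pi)) - 0.5 * z**2
        if f is Family.LOGLOGISTIC:
            g, lam = p
            # f(t) = lam*g*t**(g-1) / (1 + lam*t**g)**2
            return (
                np.log(lam * g)
                + (g - 1) * np.log(t)
                - 2 * np.logaddexp(0.0, np.log(lam) + g * np.log(t))
            )
        shape, rate = p  # gamma
        return (
            shape * np.log(rate)
            - special.gammaln(shape)
            + (shape - 1) * np.log(t)
            - rate * t
        )

    def density(self, t):
        return np.exp(self.log_density(t))

    def median(self) -> float:
        """t* with S(t*) = 0.5; closed form where available."""
        f, p = self.family, self.params
        if f is Family.EXPONENTIAL:
            return float(np.log(2.0) / p[0])
        if f is Family.WEIBULL:
            return float(p[1] * np.log(2.0) ** (1.0 / p[0]))
        if f is Family.LOGNORMAL:
            return float(np.exp(p[0]))
        if f is Family.LOGLOGISTIC:
            g, lam = p
            return float((1.0 / lam) ** (1.0 / g))
        if f is Family.GOMPERTZ:
            a, b = p
            arg = 1.0 + (a / b) * np.log(2.0)
            if arg <= 0:
                raise NoMedianError(
                    f"gompertz(a={a}, b={b}) plateaus above 0.5; no median"
                )
            return float(np.log(arg) / a)
        # gamma: numeric inverse of the regularized upper incomplete gamma
        shape, rate = p
        return float(special.gammainccinv(shape, 0.5) / rate)


def survival_at(model: ParametricSurvival, t) -> float:
    """Survival probability S(t) under ``model`` at time ``t`` (months)."""
    return model.survival(t)


def median_survival(model: ParametricSurvival) -> float:
    """Median survival time in months (S crosses 0.5)."""
    return model.median()


# -- log-logistic parameterization conversions ---------------------------


def loglogistic_from_scale_form(alpha: float, beta: float) -> ParametricSurvival:
    """Convert S(t) = 1/(1 + (t/alpha)**beta) (lifelines/fisk form) to rate form."""
    return ParametricSurvival(Family.LOGLOGISTIC, (beta, alpha ** (-beta)))


def loglogistic_to_scale_form(model: ParametricSurvival) -> tuple:
    """Return (alpha, beta) of the scale form for a rate-form log-logistic."""
    if model.family is not Family.LOGLOGISTIC:
        raise SurvivalDomainError("not a log-logistic model")
    g, lam = model.params
    return (lam ** (-1.0 / g), g)


# -- pseudo individual-patient data ---------------------------------------


@dataclass
class PseudoIPD:
    """Right-censored survival records: times in months, event flag 1/0."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(~np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (event)")

    def __len__(self):
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})

    def to_csv(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())


# -- fitting ---------------------------------------------------------------


@dataclass
class FitReport:
    """Maximum-likelihood fit of one family to right-censored records."""

    family: Family
    fitted_params: tuple
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int
    converged: bool = True
    message: str = ""
    tie: bool = False

    @property
    def model(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.fitted_params)


def _neg_loglik(theta, family, times, events):
    """Negative censored log-likelihood; theta on log scale except gompertz shape."""
    try:
        model = _decode(theta, family)
    except SurvivalDomainError:
        return np.inf
    with np.errstate(all="ignore"):
        ll = np.sum(model.log_density(times[events == 1])) if np.any(events == 1) else 0.0
        cens = times[events == 0]
        if cens.size:
            s = model.survival(cens)
            if np.any(s <= 0):
                return np.inf
            ll += np.sum(np.log(s))
    return np.inf if not np.isfinite(ll) else -ll


def _decode(theta, family):
    if family is Family.EXPONENTIAL:
        return ParametricSurvival(family, (np.exp(theta[0]),))
    if family is Family.GOMPERTZ:
        # shape unconstrained (may be negative), rate positive
        return ParametricSurvival(family, (theta[0], np.exp(theta[1])))
    if family is Family.LOGNORMAL:
        return ParametricSurvival(family, (theta[0], np.exp(theta[1])))
    return ParametricSurvival(family, (np.exp(theta[0]), np.exp(theta[1])))


def _starts(family, times, events):
    """Three fixed moment-informed starting points per family."""
    t_ev = times[events == 1]
    m = float(np.mean(t_ev)) if t_ev.size else float(np.mean(times))
    m = max(m, 1e-6)
    lm = np.log(m)
    if family is Family.EXPONENTIAL:
        return [[-lm], [-lm + 1.0], [-lm - 1.0]]
    if family is Family.GOMPERTZ:
        return [[0.01, -lm], [0.1, -lm - 1.0], [-0.01, -lm]]
    if family is Family.LOGNORMAL:
        lt = np.log(np.maximum(t_ev if t_ev.size else times, 1e-6))
        mu, sig = float(np.mean(lt)), max(float(np.std(lt)), 0.1)
        return [[mu, np.log(sig)], [mu, np.log(sig * 2)], [lm, 0.0]]
    if family is Family.LOGLOGISTIC:
        # rate form: lambda ~ median**(-gamma)
        return [[np.log(g), -g * lm] for g in (1.0, 2.0, 0.5)]
    # weibull (shape, scale) / gamma (shape, rate)
    if family is Family.WEIBULL:
        return [[0.0, lm], [np.log(2.0), lm], [np.log(0.5), lm]]
    return [[0.0, -lm], [np.log(2.0), np.log(2.0) - lm], [np.log(0.5), np.log(0.5) - lm]]


def fit_mle(data: PseudoIPD, family: Family) -> FitReport:
    """Censored MLE of ``family`` on pseudo-IPD.

    Likelihood: prod f(t_i)^event_i * S(t_i)^(1-event_i).  The optimizer is
    restarted from three fixed starting points; the best converged likelihood
    is kept.  Non-convergence yields a report with ``converged=False`` and the
    optimizer diagnostics in ``message`` — never a silent fallback.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 records to fit")
    if data.n_events < 1:
        raise ValueError("need at least one event record to fit")
    times = np.maximum(data.times, 1e-9)  # guard exact zeros in log-densities
    events = data.events

    best, best_val = None, np.inf
    msgs = []
    for x0 in _starts(family, times, events):
        res = optimize.minimize(
            _neg_loglik, x0=np.asarray(x0, dtype=float),
            args=(family, times, events), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        msgs.append(res.message)
        if res.fun < best_val and np.isfinite(res.fun):
            best, best_val = res, res.fun
    if best is None:
        return FitReport(family, (), -np.inf, np.inf, np.inf, len(data),
                         converged=False, message="; ".join(map(str, msgs)))
    model = _decode(best.x, family)
    ll = -best_val
    k = N_PARAMS[family]
    return FitReport(
        family=family,
        fitted_params=tuple(float(v) for v in model.params),
        log_likelihood=float(ll),
        aic=float(2 * k - 2 * ll),
        bic=float(k * np.log(len(data)) - 2 * ll),
        n_obs=len(data),
        converged=bool(best.success),
        message=str(best.message),
    )


def fit_all(data: PseudoIPD, families=tuple(Family)) -> list:
    return [fit_mle(data, f) for f in families]


def select_best(reports, criterion: str = "aic") -> FitReport:
    """Report with the minimal AIC/BIC; ties broken by Family enum order."""
    reports = list(reports)
    if not reports:
        raise ValueError("no fit reports to select from")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    order = {f: i for i, f in enumerate(Family)}
    key = lambda r: (getattr(r, criterion), order[r.family])
    best = min(reports, key=key)
    tied = [r for r in reports
            if r is not best and getattr(r, criterion) == getattr(best, criterion)]
    if tied:
        best = replace(best, tie=True)
    return best


def fit_least_squares(times, probs, family: Family = Family.LOGLOGISTIC) -> ParametricSurvival:
    """Least-squares fit of a survival curve to digitized (t, S) coordinates."""
    times = np.asarray(times, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if family is not Family.LOGLOGISTIC:
        raise NotImplementedError("least-squares refit implemented for log-logistic")
    mask = times > 0

    def s_fun(t, g, lam):
        return 1.0 / (1.0 + lam * t**g)

    popt, _ = optimize.curve_fit(
        s_fun, times[mask], probs[mask], p0=(1.5, 0.01),
        bounds=([1e-6, 1e-12], [50.0, 1e6]), maxfev=10000,
    )
    return ParametricSurvival(Family.LOGLOGISTIC, tuple(float(v) for v in popt))
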