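"""Parametric catheter-survival fitting with AIC-based family selection.

Right-censored maximum likelihood for four families — exponential, Weibull,
lognormal and Gompertz — through one generic routine over scipy.stats
log-densities: removal events contribute log f(t), censored observations
log S(t). A single likelihood convention keeps AIC comparable across
families, which is the whole point of the selection step. The Kaplan–Meier
estimator (via lifelines) is provided as a nonparametric cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import optimize, stats
from scipy.special import log_ndtr

__all__ = [
    "FAMILIES",
    "FittedSurvival",
    "KMEstimate",
    "fit_parametric",
    "fit_all",
    "select_family",
    "km_estimate",
]

FAMILIES = ("exponential", "weibull", "lognormal", "gompertz")

#: number of free parameters per family
_N_PARAMS = {"exponential": 1, "weibull": 2, "lognormal": 2, "gompertz": 2}

_MIN_EVENTS = 10

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class FittedSurvival:
    """One maximum-likelihood parametric fit.

    ``params`` uses natural parameterizations: exponential {rate}; weibull
    {shape, scale}; lognormal {mu, sigma}; gompertz {shape, rate} with
    hazard h(t) = rate * exp(shape * t).
    """

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    median: float
    n: int
    n_events: int
    converged: bool = True
    _fingerprint: tuple = field(default=(), repr=False)

    def _frozen(self):
        return _frozen_dist(self.family, self.params)

    def sf(self, t):
        """Survivor function S(t) under the fitted parameters."""
        return self._frozen().sf(t)

    def pdf(self, t):
        return self._frozen().pdf(t)


def _frozen_dist(family: str, p: dict[str, float]):
    if family == "exponential":
        return stats.expon(scale=1.0 / p["rate"])
    if family == "weibull":
        return stats.weibull_min(p["shape"], scale=p["scale"])
    if family == "lognormal":
        return stats.lognorm(p["sigma"], scale=math.exp(p["mu"]))
    if family == "gompertz":
        # scipy's gompertz: S(x) = exp(-c (e^{x/scale} - 1)) with c = rate/shape
        return stats.gompertz(p["rate"] / p["shape"], scale=1.0 / p["shape"])
    raise ValueError(f"unknown family {family!r}")


def _natural_params(family: str, theta: np.ndarray) -> dict[str, float]:
    if family == "exponential":
        return {"rate": math.exp(theta[0])}
    if family == "weibull":
        return {"shape": math.exp(theta[0]), "scale": math.exp(theta[1])}
    if family == "lognormal":
        return {"mu": theta[0], "sigma": math.exp(theta[1])}
    if family == "gompertz":
        return {"shape": math.exp(theta[0]), "rate": math.exp(theta[1])}
    raise ValueError(f"unknown family {family!r}")


def _negloglik(theta, family, t_event, t_cens):
    """Explicit censored log-likelihoods (vectorized; events contribute
    log f, censored observations log S). Kept in closed form for speed; the
    scipy.stats equivalents back the fitted objects and the tests."""
    with np.errstate(over="ignore", invalid="ignore"):
        if family == "exponential":
            rate = math.exp(theta[0])
            ll = t_event.size * math.log(rate) - rate * (t_event.sum() + t_cens.sum())
        elif family == "weibull":
            c, s = math.exp(theta[0]), math.exp(theta[1])
            z_e, z_c = t_event / s, t_cens / s
            ll = (t_event.size * math.log(c / s) + (c - 1.0) * np.log(z_e).sum()
                  - np.power(z_e, c).sum() - (np.power(z_c, c).sum() if z_c.size else 0.0))
        elif family == "lognormal":
            mu, sigma = theta[0], math.exp(theta[1])
            z = (np.log(t_event) - mu) / sigma
            ll = (-np.log(t_event).sum() - t_event.size * math.log(sigma * _SQRT2PI)
                  - 0.5 * (z * z).sum())
            if t_cens.size:
                ll += log_ndtr((mu - np.log(t_cens)) / sigma).sum()
        elif family == "gompertz":
            a, b = math.exp(theta[0]), math.exp(theta[1])
            cum_e = (b / a) * np.expm1(a * t_event)
            ll = (t_event.size * math.log(b) + a * t_event.sum() - cum_e.sum())
            if t_cens.size:
                ll -= ((b / a) * np.expm1(a * t_cens)).sum()
        else:  # pragma: no cover
            raise ValueError(family)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _starts(family: str, t_event: np.ndarray, t_all: np.ndarray,
            n_events: int) -> list[np.ndarray]:
    """Deterministic multi-start grid of initializations."""
    total_time = float(t_all.sum())
    rate0 = n_events / total_time  # exponential MLE, exact under censoring
    med = float(np.median(t_event))
    if family == "exponential":
        return [np.array([math.log(rate0)])]
    if family == "weibull":
        scale0 = 1.0 / rate0
        return [np.array([math.log(c), math.log(scale0)]) for c in (0.5, 1.0, 2.0)]
    if family == "lognormal":
        logs = np.log(t_event)
        mu0, s0 = float(logs.mean()), max(float(logs.std()), 1e-3)
        return [np.array([mu0, math.log(s0)]),
                np.array([math.log(med), math.log(1.0)])]
    if family == "gompertz":
        starts = []
        for a in (0.25, 1.0, 4.0):
            shape = a / max(med, 1e-12)  # scale the shape grid to the data's time unit
            b = shape * math.log(2) / math.expm1(shape * med)
            starts.append(np.array([math.log(shape), math.log(b)]))
        starts.append(np.array([math.log(1e-3 / max(med, 1e-12)), math.log(rate0)]))
        return starts
    raise ValueError(f"unknown family {family!r}")


def fit_parametric(times: Sequence[float], events: Sequence[bool] | Sequence[int],
                   family: str) -> FittedSurvival:
    """Censored MLE of one family. ``events`` flags removals (1) vs censored (0)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if np.any(t <= 0):
        raise ValueError("all times must be > 0")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("all observations censored; cannot fit")
    if n_events < _MIN_EVENTS:
        raise ValueError(f"need at least {_MIN_EVENTS} uncensored events, got {n_events}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r} (choose from {FAMILIES})")

    t_event, t_cens = t[e], t[~e]
    best = None
    diagnostics = []
    for x0 in _starts(family, t_event, t, n_events):
        res = optimize.minimize(
            _negloglik, x0, args=(family, t_event, t_cens),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 4000})
        diagnostics.append(res.message)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"{family} fit failed to converge: {diagnostics}")

    params = _natural_params(family, best.x)
    ll = -best.fun
    k = _N_PARAMS[family]
    dist = _frozen_dist(family, params)
    return FittedSurvival(
        family=family, params=params, loglik=ll, aic=2 * k - 2 * ll,
        median=float(dist.ppf(0.5)), n=int(t.size), n_events=n_events,
        converged=bool(best.success),
        _fingerprint=(int(t.size), n_events, round(float(t.sum()), 9)),
    )


def fit_all(times, events, families: Sequence[str] = FAMILIES) -> list[FittedSurvival]:
    """Fit every requested family to the same data."""
    return [fit_parametric(times, events, f) for f in families]


def select_family(fits: Sequence[FittedSurvival]) -> str:
    """Minimum-AIC family; ties broken toward fewer parameters.

    All fits must be over identical data (checked via a data fingerprint).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    prints = {f._fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits are over different data; AICs are not comparable")
    return min(fits, key=lambda f: (f.aic, _N_PARAMS[f.family])).family


@dataclass
class KMEstimate:
    """Kaplan–Meier product-limit estimate with its median."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # nan when S never reaches 0.5
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return not math.isnan(self.median)


def km_estimate(times, events) -> KMEstimate:
    """Nonparametric survivor curve; median = first time with S <= 0.5."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    med = float(kmf.median_survival_time_)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=med if math.isfinite(med) else float("nan"),
        n=int(t.size), n_events=int(e.sum()),
    )
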