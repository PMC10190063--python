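"""Synthetic patient-level cohort generator.

No patient-level dataset is distributed with the source analysis, so this
module simulates one with the statistical structure the downstream pipeline
assumes: eleven matching covariates, device assignment confounded on those
covariates through a multinomial logit (so the raw groups are imbalanced
and propensity-score matching has work to do), per-device Bernoulli
complication events with categorical type mixes, gamma-distributed itemized
costs, lognormal (CVC) or Gompertz (PICC/IVAP) catheter survival, and CVC
reinsertion cycles. Because the generator knows its own truth
(a ``ModelParameters`` object), parameter-recovery tests can close the loop
cohort -> estimation -> decision model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (ARM_NAMES, ModelParameters, default_parameters,
                         gompertz_rate_from_median)

__all__ = ["GeneratorConfig", "COHORT_COLUMNS", "COVARIATES",
           "generate_cohort", "write_cohort", "read_cohort"]

#: The eleven matching covariates.
COVARIATES = ("age", "sex", "ethnicity", "education", "height", "weight",
              "hypertension", "hyperlipidemia", "smoking",
              "allergy_history", "thrombosis_history")

CATEGORICAL_COVARIATES = ("sex", "ethnicity", "education")

COHORT_COLUMNS = ("id",) + COVARIATES + (
    "device", "insertion_cost", "maintenance_cost_total", "removal_cost",
    "had_complication", "complication_type", "complication_cost",
    "survival_time", "event", "n_insertions")

_NUMERIC_COLUMNS = ("age", "height", "weight", "insertion_cost",
                    "maintenance_cost_total", "removal_cost",
                    "complication_cost", "survival_time")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``n_per_arm`` are expected pre-matching arm sizes (defaults sum to the
    source study's 10,718 eligible patients); ``confounding`` maps covariate
    names to log-odds effects (per SD for continuous covariates) pushing
    assignment toward IVAP and away from PICC, which produces the baseline
    imbalance matching is meant to remove.
    """

    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"CVC": 4823, "PICC": 1608, "IVAP": 4287})
    truth: ModelParameters = field(default_factory=default_parameters)
    confounding: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "weight": 0.15,
                                 "hypertension": 0.2, "thrombosis_history": 0.4})
    censoring_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_arm) != set(ARM_NAMES):
            raise ValueError(f"n_per_arm must cover {ARM_NAMES}")
        if any(n <= 0 for n in self.n_per_arm.values()):
            raise ValueError("arm sizes must be > 0")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        unknown = set(self.confounding) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown confounding covariates: {sorted(unknown)}")


def _gamma_draw(rng, mean, sd, size):
    """Gamma draws with the given mean/SD (point mass when sd == 0)."""
    if sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size)


def _censoring_rate(t_latent: np.ndarray, fraction: float) -> float:
    """Exponential censoring rate giving the target expected censored share.

    Solves mean_i[1 - exp(-lam * t_i)] = fraction over the latent times.
    """
    from scipy import optimize

    def gap(log_lam):
        return float(np.mean(-np.expm1(-math.exp(log_lam) * t_latent))) - fraction

    log_lam = optimize.brentq(gap, -40.0, 40.0, xtol=1e-12)
    return math.exp(log_lam)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "age": np.clip(rng.normal(50.0, 10.0, n), 18.0, 85.0).round(1),
        "sex": rng.choice(["female", "male"], n, p=[0.995, 0.005]),
        "ethnicity": rng.choice(["Han", "other"], n, p=[0.93, 0.07]),
        "education": rng.choice(["primary", "secondary", "tertiary"], n,
                                p=[0.30, 0.45, 0.25]),
        "height": rng.normal(158.5, 5.8, n).round(1),
        "weight": rng.normal(59.8, 8.9, n).round(1),
        "hypertension": rng.binomial(1, 0.18, n),
        "hyperlipidemia": rng.binomial(1, 0.12, n),
        "smoking": rng.binomial(1, 0.05, n),
        "allergy_history": rng.binomial(1, 0.10, n),
        "thrombosis_history": rng.binomial(1, 0.04, n),
    })


def _assign_devices(rng, cov: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    n = len(cov)
    total = sum(config.n_per_arm.values())
    shares = {a: config.n_per_arm[a] / total for a in ARM_NAMES}
    # standardized linear signal shared by all confounders
    signal = np.zeros(n)
    for name, beta in config.confounding.items():
        x = cov[name]
        if name in CATEGORICAL_COVARIATES:
            x = (x == x.mode().iloc[0]).astype(float)
        x = np.asarray(x, dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        signal += beta * z
    # multinomial logit: confounders push toward IVAP and away from PICC
    eta = np.column_stack([
        np.full(n, math.log(shares["CVC"])),
        math.log(shares["PICC"]) - signal,
        math.log(shares["IVAP"]) + signal,
    ])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    cum = np.cumsum(p, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(ARM_NAMES)[idx]


def _draw_survival(rng, arm, truth: ModelParameters, size) -> np.ndarray:
    spec = truth.arms[arm].survival
    if spec.family == "lognormal":
        sigma = spec.fitted_params.get("sigma", 0.5)
        return rng.lognormal(math.log(spec.median), sigma, size)
    if spec.family == "gompertz":
        a = spec.fitted_params.get("shape", 1.0)
        b = gompertz_rate_from_median(a, spec.median)
        u = rng.uniform(size=size)
        arg = 1.0 - (a / b) * np.log(u)
        if np.any(arg <= 0):
            raise ValueError("gompertz parameters inconsistent with the requested median")
        return np.log(arg) / a
    if spec.family == "exponential":
        return rng.exponential(spec.median / math.log(2), size)
    if spec.family == "weibull":
        shape = spec.fitted_params.get("shape", 1.5)
        scale = spec.median / math.log(2) ** (1.0 / shape)
        return scale * rng.weibull(shape, size)
    raise ValueError(f"unknown survival family {spec.family!r}")


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a patient-level cohort under the configured truth.

    Deterministic under a fixed seed. Complication flags are Bernoulli with
    the arm's probability; types follow the arm's constituent mix; itemized
    costs are gamma with the truth means and patient-level SDs; survival
    follows the arm's parametric family with the truth median; censoring is
    an independent exponential time whose rate is calibrated so the expected
    censored share equals ``censoring_fraction``. CVC patients
    carry 1 + Poisson(mean_insertions - 1) catheter episodes whose episode
    costs accumulate into the cost columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    n = sum(config.n_per_arm.values())

    cov = _draw_covariates(rng, n)
    device = _assign_devices(rng, cov, config)

    df = cov.copy()
    df.insert(0, "id", np.arange(n))
    df["device"] = device
    for col in ("insertion_cost", "maintenance_cost_total", "removal_cost",
                "complication_cost", "survival_time"):
        df[col] = 0.0
    df["had_complication"] = False
    df["complication_type"] = "none"
    df["event"] = "removal"
    df["n_insertions"] = pd.array([pd.NA] * n, dtype="Int64")

    for arm in ARM_NAMES:
        mask = device == arm
        m = int(mask.sum())
        if m == 0:
            continue
        ap = truth.arms[arm]

        # catheter survival (uncensored latent time)
        t_latent = _draw_survival(rng, arm, truth, m)

        # independent exponential censoring, rate calibrated so the expected
        # censored share equals the configured fraction (independence keeps
        # the censored-likelihood MLE unbiased)
        if config.censoring_fraction > 0:
            lam = _censoring_rate(t_latent, config.censoring_fraction)
            c = rng.exponential(1.0 / lam, m)
            censored = c < t_latent
            t_obs = np.minimum(t_latent, c)
        else:
            censored = np.zeros(m, dtype=bool)
            t_obs = t_latent

        if arm == "CVC":
            k = 1 + rng.poisson(truth.cvc_extras.mean_insertions - 1.0, m)
            # sum of k iid gamma episode costs == gamma with k-fold shape
            for col, cp in (("insertion_cost", ap.insertion),
                            ("maintenance_cost_total", ap.maintenance),
                            ("removal_cost", ap.removal)):
                sd = cp.patient_sd
                shape = (cp.mean / sd) ** 2
                scale = sd ** 2 / cp.mean
                df.loc[mask, col] = rng.gamma(k * shape, scale)
            df.loc[mask, "n_insertions"] = k
        else:
            df.loc[mask, "insertion_cost"] = _gamma_draw(
                rng, ap.insertion.mean, ap.insertion.patient_sd, m)
            per_visit = _gamma_draw(rng, ap.maintenance.mean, ap.maintenance.patient_sd, m)
            visits = t_obs / ap.maintenance_interval
            df.loc[mask, "maintenance_cost_total"] = per_visit * visits
            df.loc[mask, "removal_cost"] = _gamma_draw(
                rng, ap.removal.mean, ap.removal.patient_sd, m)

        df.loc[mask, "survival_time"] = t_obs
        df.loc[mask, "event"] = np.where(censored, "censored", "removal")

        # complications: Bernoulli incidence, categorical type, gamma cost
        prof = ap.complications
        hit = rng.uniform(size=m) < prof.probability
        types = sorted(prof.mix)
        probs = np.array([prof.mix[t] for t in types])
        chosen = rng.choice(types, size=m, p=probs / probs.sum())
        cost = np.zeros(m)
        for t in types:
            sel = hit & (chosen == t)
            if sel.any():
                cp = prof.type_costs[t]
                cost[sel] = _gamma_draw(rng, cp.mean, cp.patient_sd, int(sel.sum()))
        df.loc[mask, "had_complication"] = hit
        col_idx = df.columns.get_loc("complication_type")
        df.iloc[np.where(mask)[0], col_idx] = np.where(hit, chosen, "none")
        df.loc[mask, "complication_cost"] = cost

    return df[list(COHORT_COLUMNS)]


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with the fixed documented header."""
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (round-trips :func:`write_cohort`)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"complication_type": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty cohort file") from None
    if df.empty:
        raise ValueError(f"{path}: cohort has no rows")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    df["had_complication"] = df["had_complication"].astype(bool)
    df["n_insertions"] = df["n_insertions"].astype("Int64")
    is_cvc = df["device"] == "CVC"
    if df.loc[is_cvc, "n_insertions"].isna().any():
        raise ValueError(f"{path}: CVC rows must carry n_insertions")
    return df[list(COHORT_COLUMNS)]
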