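"""Deterministic (one-way tornado) and probabilistic sensitivity analysis.

The one-way analysis moves each eligible parameter to its 95% CI bounds
(or +/-10% when no CI is printed) with everything else at base case and
records the excursion of the designated pairwise ICER. The probabilistic
analysis draws every parameter from its assigned distribution (gamma for
costs, beta for utilities and complication probabilities — the latter from
event counts — normals for the CVC cycle statistics, median-survival
sampling through the fitted lognormal/Gompertz families), evaluates the
decision tree per draw, and summarizes the draws as cost-effectiveness
acceptability curves and incremental scatter clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import tree
from .cea import icer, nmb, recommend
from .parameters import (ARM_NAMES, DSA_KEYS, ModelParameters,
                         assigned_distribution, derive_sampling_distribution,
                         dsa_bounds)
from .tree import FULL, ArmOutcome, evaluate_arm

__all__ = ["TornadoEntry", "PSADraws", "CEACPoint", "one_way_dsa",
           "sample_psa", "ceac", "psa_scatter", "default_wtp_grid"]


@dataclass
class TornadoEntry:
    """One parameter's one-way excursion of the designated pairwise ICER."""

    key: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _pair_icer(params: ModelParameters, pair: tuple[str, str],
               dwell=FULL) -> float:
    a = evaluate_arm(params, pair[0], dwell)
    b = evaluate_arm(params, pair[1], dwell)
    comp = icer(a, b)
    return comp.icer if comp.icer is not None else float("nan")


def one_way_dsa(params: ModelParameters, pair: tuple[str, str] = ("IVAP", "CVC"),
                keys: Sequence[str] | None = None, dwell=FULL) -> list[TornadoEntry]:
    """Tornado entries sorted by descending ICER spread.

    A dominance flag at an excursion endpoint (increments of opposite sign,
    so no ratio exists) is recorded as NaN for that endpoint.
    """
    keys = tuple(keys) if keys is not None else DSA_KEYS
    entries = []
    for key in keys:
        lo, hi = dsa_bounds(params, key)
        out_lo = _pair_icer(params.with_value(key, lo), pair, dwell)
        out_hi = _pair_icer(params.with_value(key, hi), pair, dwell)
        entries.append(TornadoEntry(key, lo, hi, out_lo, out_hi))
    entries.sort(key=lambda e: -e.spread)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": e.key, "low": e.low, "high": e.high,
          "outcome_low": e.outcome_low, "outcome_high": e.outcome_high,
          "spread": e.spread} for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _psa_distribution(params: ModelParameters, key: str):
    """The PSA sampling rule for one parameter key."""
    fam = assigned_distribution(key)
    spec = params.spec_for(key)
    if fam == "gamma":
        return derive_sampling_distribution(spec, "gamma")
    if fam == "beta":
        if key.startswith("p"):  # complication probability: beta from counts
            return derive_sampling_distribution(spec, "beta")
        return derive_sampling_distribution(spec, "beta")
    if fam == "normal":
        lower = 1.0 if key == "CVC_mean_insertionTimes" else 0.0
        return derive_sampling_distribution(spec, "normal", lower=lower)
    if fam == "lognormal":
        return derive_sampling_distribution(spec, "lognormal-median")
    if fam == "gompertz":
        return derive_sampling_distribution(spec, "gompertz-median")
    raise ValueError(f"parameter {key!r} has no PSA distribution")


@dataclass
class PSADraws:
    """Sampled parameter sets with their per-arm decision-tree outcomes."""

    params: pd.DataFrame            # n_draws x parameter keys
    outcomes: dict[str, pd.DataFrame]  # arm -> DataFrame(cost, qaly)
    seed: int | None
    dwell: object = FULL

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def arm_outcomes(self, i: int) -> list[ArmOutcome]:
        """Scalar outcomes of draw ``i`` (for cross-checks and decisions)."""
        return [ArmOutcome(a, self.dwell,
                           float(self.outcomes[a]["cost"].iloc[i]),
                           float(self.outcomes[a]["qaly"].iloc[i]))
                for a in ARM_NAMES]


def _evaluate_draws(params: ModelParameters, draws: pd.DataFrame,
                    dwell=FULL) -> dict[str, pd.DataFrame]:
    """Vectorized decision-tree evaluation over sampled parameter columns.

    Mirrors :mod:`vadcea.tree` arithmetic on numpy arrays; the agreement of
    the two routes is asserted in the test suite.
    """
    g = draws.__getitem__
    out = {}
    for arm in ARM_NAMES:
        ap = params.arms[arm]
        pnum = {"CVC": "1", "PICC": "2", "IVAP": "3"}[arm]
        cpre = {"CVC": "c1_CVC", "PICC": "c2_PICC", "IVAP": "c3_IVAP"}[arm]
        upre = {"CVC": "u1_CVC", "PICC": "u2_PICC", "IVAP": "u3_IVAP"}[arm]
        p = g(f"p{pnum}_{arm}_complication").to_numpy()
        u = g(upre).to_numpy()
        u_comp = g(f"{upre}_complication").to_numpy()
        wu = p * u_comp + (1.0 - p) * u
        per_event = sum(share * g(f"c_complication_{t}").to_numpy()
                        for t, share in ap.complications.mix.items())
        comp_cost = p * per_event
        if arm == "CVC":
            k = g("CVC_mean_insertionTimes").to_numpy()
            t1 = g("T1_CVC_medianSurvivalTime").to_numpy()
            episode = (g("c1_CVC_insertion").to_numpy()
                       + g("c1_CVC_maintenance").to_numpy()
                       + g("c1_CVC_removal").to_numpy())
            cost = k * episode + comp_cost
            qaly = (k * t1 * wu
                    + g("CVC_intervals").to_numpy()
                    * g("CVC_intermission").to_numpy()
                    * g("u1_CVC_intermission").to_numpy())
        else:
            med = g(f"T{pnum}_{arm}_medianSurvivalTime").to_numpy()
            t = med if dwell == FULL else np.minimum(tree.dwell_years(dwell, params), med)
            maint_key = f"{cpre}_perMaintenance"
            cost = (g(f"{cpre}_insertion").to_numpy()
                    + (t / ap.maintenance_interval) * g(maint_key).to_numpy()
                    + g(f"{cpre}_removal").to_numpy()
                    + comp_cost)
            qaly = t * wu
        out[arm] = pd.DataFrame({"cost": cost, "qaly": qaly})
    return out


def sample_psa(params: ModelParameters, n: int = 1000, seed: int | None = 0,
               dwell=FULL, keys: Sequence[str] | None = None) -> PSADraws:
    """Monte-Carlo parameter sampling with per-draw arm outcomes.

    Each of the eligible parameters is drawn independently from its
    assigned family (complication-type mixes stay fixed; only the overall
    probabilities are sampled). Reproducible under ``seed``.
    """
    keys = tuple(keys) if keys is not None else DSA_KEYS
    rng = np.random.default_rng(seed)
    cols = {}
    for key in keys:  # draw in key order for reproducibility
        try:
            dist = _psa_distribution(params, key)
        except Exception as exc:
            raise ValueError(f"cannot derive PSA distribution for {key!r}: {exc}") from exc
        cols[key] = np.asarray(dist.rvs(rng, n), dtype=float)
    draws = pd.DataFrame(cols)
    outcomes = _evaluate_draws(params, draws, dwell)
    return PSADraws(params=draws, outcomes=outcomes, seed=seed, dwell=dwell)


@dataclass
class CEACPoint:
    """Probability each arm is optimal (max NMB) at one WTP value."""

    wtp: float
    probability: dict[str, float] = field(default_factory=dict)


def default_wtp_grid(n: int = 200, top: float = 40000.0) -> np.ndarray:
    """0 to 40,000 USD/QALY, spanning the decision-relevant thresholds."""
    return np.linspace(0.0, top, n + 1)


def ceac(draws: PSADraws, wtp_grid: Sequence[float] | None = None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curves over PSA draws."""
    if draws.n_draws == 0:
        raise ValueError("no PSA draws")
    grid = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid())
    costs = np.column_stack([draws.outcomes[a]["cost"].to_numpy() for a in ARM_NAMES])
    qalys = np.column_stack([draws.outcomes[a]["qaly"].to_numpy() for a in ARM_NAMES])
    points = []
    for w in grid:
        net = w * qalys - costs
        best = np.argmax(net, axis=1)
        probs = {a: float(np.mean(best == i)) for i, a in enumerate(ARM_NAMES)}
        points.append(CEACPoint(wtp=float(w), probability=probs))
    return points


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"wtp": p.wtp, **{f"p_{a}": p.probability[a] for a in ARM_NAMES}}
                         for p in points])


def psa_scatter(draws: PSADraws, reference: str = "CVC") -> dict[str, pd.DataFrame]:
    """Per-draw incremental (delta QALY, delta cost) clouds vs a reference arm."""
    if reference not in ARM_NAMES:
        raise ValueError(f"unknown reference arm {reference!r}")
    ref_c = draws.outcomes[reference]["cost"].to_numpy()
    ref_q = draws.outcomes[reference]["qaly"].to_numpy()
    out = {}
    for arm in ARM_NAMES:
        if arm == reference:
            continue
        out[arm] = pd.DataFrame({
            "delta_qaly": draws.outcomes[arm]["qaly"].to_numpy() - ref_q,
            "delta_cost": draws.outcomes[arm]["cost"].to_numpy() - ref_c,
        })
    return out
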