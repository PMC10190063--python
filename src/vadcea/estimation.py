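"""From a (matched) cohort to model parameters.

Rebuilds the decision model's inputs from patient-level data: itemized cost
means/SDs per arm, complication incidence (patients with at least one
complication) with its per-type constituent mix and per-type cost means,
AIC-selected parametric survival medians, and the CVC cycle statistics.
Utility weights are survey-derived inputs, not cohort columns, so they are
carried over from a base parameter set. Also provides the Pearson
chi-square comparison used for the complication-incidence contrast.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as surv
from .parameters import (ARM_NAMES, ArmParams, ComplicationProfile, CostParam,
                         ModelParameters, SurvivalSpec, default_parameters)

__all__ = ["ChiSquareResult", "complication_mix", "chi_square_test",
           "estimate_arm_parameters", "estimate_parameters"]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def complication_mix(counts: Mapping[str, int]) -> dict[str, float]:
    """Constituent ratios: per-type share of complication events."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complication events; mix undefined")
    return {t: c / total for t, c in counts.items()}


def chi_square_test(contingency) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table (no continuity correction)."""
    table = np.asarray(contingency, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(res[0]), df=int(res[2]), p=float(res[1]))


def _cost_from_column(values: np.ndarray, label: str) -> CostParam:
    return CostParam(mean=float(np.mean(values)),
                     sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
                     label=label)


def estimate_arm_parameters(cohort: pd.DataFrame, arm: str,
                            survival_fit: surv.FittedSurvival | None = None,
                            base: ModelParameters | None = None,
                            event_labels: tuple[str, ...] = ("removal",)) -> ArmParams:
    """Estimate one arm's parameters from patient-level records.

    CVC cost components are normalized per insertion episode (column totals
    divided by each patient's ``n_insertions``); PICC/IVAP maintenance is
    per visit (totals divided by observed dwell / maintenance interval).
    When no ``survival_fit`` is passed, all four families are fitted and the
    minimum-AIC one selected; ``event_labels`` names the ``event`` values
    treated as removal events (everything else censors), so alternative
    event conventions — e.g. counting only unplanned removals — plug in
    directly. Utilities come from ``base`` (default: packaged values)
    because they are survey inputs, not cohort columns.
    """
    base = base if base is not None else default_parameters()
    sub = cohort[cohort["device"] == arm]
    if sub.empty:
        raise ValueError(f"no patients in arm {arm!r}")
    template = base.arms[arm]

    if arm == "CVC":
        k = sub["n_insertions"].astype(float).to_numpy()
        insertion = _cost_from_column(sub["insertion_cost"].to_numpy() / k, "c1_CVC_insertion")
        maintenance = _cost_from_column(
            sub["maintenance_cost_total"].to_numpy() / k, "c1_CVC_maintenance")
        removal = _cost_from_column(sub["removal_cost"].to_numpy() / k, "c1_CVC_removal")
    else:
        insertion = _cost_from_column(sub["insertion_cost"].to_numpy(), f"{arm} insertion")
        visits = sub["survival_time"].to_numpy() / template.maintenance_interval
        ok = visits > 0
        maintenance = _cost_from_column(
            (sub["maintenance_cost_total"].to_numpy()[ok]) / visits[ok],
            f"{arm} per-maintenance")
        removal = _cost_from_column(sub["removal_cost"].to_numpy(), f"{arm} removal")

    with_comp = sub[sub["had_complication"]]
    counts = with_comp["complication_type"].value_counts().to_dict()
    n_events = int(len(with_comp))
    mix = complication_mix(counts) if n_events else {}
    type_costs = {}
    for t in counts:
        vals = with_comp.loc[with_comp["complication_type"] == t,
                             "complication_cost"].to_numpy()
        type_costs[t] = _cost_from_column(vals, f"c_complication_{t}")
    profile = ComplicationProfile(
        probability=n_events / len(sub), n_events=n_events or None,
        n_patients=len(sub), counts=counts, mix=mix, type_costs=type_costs)

    if survival_fit is None:
        fits = surv.fit_all(sub["survival_time"].to_numpy(),
                            sub["event"].isin(event_labels).to_numpy())
        family = surv.select_family(fits)
        survival_fit = next(f for f in fits if f.family == family)
    spec = SurvivalSpec(median=survival_fit.median, family=survival_fit.family,
                        fitted_params=dict(survival_fit.params))

    return ArmParams(
        name=arm, insertion=insertion, maintenance=maintenance, removal=removal,
        complications=profile,
        utility=copy.deepcopy(template.utility),
        utility_with_complication=copy.deepcopy(template.utility_with_complication),
        survival=spec,
        maintenance_interval=template.maintenance_interval,
    )


def estimate_parameters(cohort: pd.DataFrame,
                        base: ModelParameters | None = None) -> ModelParameters:
    """Estimate the full parameter set from a cohort.

    The CVC cycle statistics (mean insertions, intermissions) come from the
    ``n_insertions`` column; intermission duration and utility, like all
    utilities and the willingness-to-pay threshold, are survey/threshold
    inputs carried over from ``base``.
    """
    base = base if base is not None else default_parameters()
    out = copy.deepcopy(base)
    for arm in ARM_NAMES:
        out.arms[arm] = estimate_arm_parameters(cohort, arm, base=base)
    k = cohort.loc[cohort["device"] == "CVC", "n_insertions"].astype(float)
    if len(k):
        out.cvc_extras.mean_insertions = float(k.mean())
        out.cvc_extras.n_intermissions = float(k.mean()) - 1.0
    return out


def complication_contingency(cohort_or_counts) -> np.ndarray:
    """3 x 2 table [with, without] complications per arm.

    Accepts a cohort DataFrame or a mapping arm -> (n_events, n_patients).
    """
    rows = []
    if isinstance(cohort_or_counts, pd.DataFrame):
        for arm in ARM_NAMES:
            sub = cohort_or_counts[cohort_or_counts["device"] == arm]
            e = int(sub["had_complication"].sum())
            rows.append([e, len(sub) - e])
    else:
        for arm in ARM_NAMES:
            e, n = cohort_or_counts[arm]
            rows.append([e, n - e])
    return np.asarray(rows)
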