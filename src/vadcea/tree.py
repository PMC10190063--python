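"""Decision-tree evaluation: expected cost and QALYs per device arm.

The model is a single-shot decision tree. Each arm splits into
complication / no-complication branches, and the complication branch into
per-type branches weighted by the observed constituent ratio. Expected cost
is insertion + maintenance + removal + expected complication-management
cost; expected effectiveness is catheter-time multiplied by the
complication-weighted utility. The CVC arm is a composite: a patient cycles
through ``mean_insertions`` short catheter episodes separated by
intermissions lived at a (lower) intermission utility, so its outcome spans
the whole chemotherapy course and does not depend on the dwell scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .parameters import ArmParams, CvcExtras, ModelParameters

__all__ = [
    "ArmOutcome",
    "weighted_utility",
    "expected_complication_cost",
    "evaluate_simple_arm",
    "evaluate_cvc",
    "evaluate_arm",
    "scenario_table",
    "dwell_years",
    "FULL",
]

#: Sentinel dwell meaning "the full course" (catheter kept to its median
#: survival; for CVC, the whole multi-insertion cycle).
FULL = "full"


@dataclass
class ArmOutcome:
    """Expected cost (USD) and QALYs of one arm at one dwell scenario."""

    arm: str
    dwell: float | str
    expected_cost: float
    expected_qaly: float
    cost_components: dict[str, float] = field(default_factory=dict)
    qaly_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cost_components:
            assert abs(sum(self.cost_components.values()) - self.expected_cost) < 1e-9
        assert self.expected_qaly >= 0.0


def dwell_years(dwell: float | str, params: ModelParameters | None = None) -> float | str:
    """Translate a dwell label to years: '6m' -> 180/365, '12m' -> 1.0.

    Months are 30-day months and years 365-day years, except that whole
    multiples of 12 months are whole years (so "6 months" is 180 days but
    "12 months" is a full 365-day year); numeric dwells are taken as years;
    ``FULL`` passes through.
    """
    if dwell == FULL:
        return FULL
    if isinstance(dwell, str):
        dpm = params.days_per_month if params else 30.0
        dpy = params.days_per_year if params else 365.0
        if dwell.endswith("m"):
            months = float(dwell[:-1])
            if months % 12 == 0:
                return months / 12.0
            return months * dpm / dpy
        if dwell.endswith("y"):
            return float(dwell[:-1])
        raise ValueError(f"cannot parse dwell {dwell!r} (use e.g. '6m', '1.5y', 'full')")
    return float(dwell)


def weighted_utility(arm: ArmParams) -> float:
    """Complication-weighted utility: p*u_comp + (1-p)*u."""
    p = arm.complications.probability
    return p * arm.utility_with_complication.mean + (1.0 - p) * arm.utility.mean


def expected_complication_cost(arm: ArmParams) -> float:
    """probability x sum over types of mix(type) * cost(type).

    Applied once per patient over the whole course: the complication branch
    of the tree realizes a single mix-weighted management cost.
    """
    prof = arm.complications
    missing = set(prof.mix) - set(prof.type_costs)
    if missing:
        raise KeyError(f"complication types lacking a cost: {sorted(missing)}")
    per_event = sum(share * prof.type_costs[t].mean for t, share in prof.mix.items())
    return prof.probability * per_event


def evaluate_simple_arm(arm: ArmParams, dwell: float | str = FULL) -> ArmOutcome:
    """Expected outcome of a single-catheter arm (PICC or IVAP).

    Effective catheter time is ``min(dwell, median survival)`` (the catheter
    cannot outlive its median dwell in expectation, and a shorter treatment
    course removes it early). Maintenance visits accrue fractionally at one
    visit per ``maintenance_interval`` years.
    """
    if arm.maintenance_interval is None or arm.maintenance_interval <= 0:
        raise ValueError(f"{arm.name}: maintenance interval must be > 0")
    t = arm.survival.median if dwell == FULL else min(float(dwell), arm.survival.median)
    if t < 0:
        raise ValueError("dwell must be >= 0")
    visits = t / arm.maintenance_interval
    comp = expected_complication_cost(arm)
    cost_parts = {
        "insertion": arm.insertion.mean,
        "maintenance": visits * arm.maintenance.mean,
        "removal": arm.removal.mean,
        "complication": comp,
    }
    qaly_parts = {"on_catheter": t * weighted_utility(arm), "intermission": 0.0}
    return ArmOutcome(arm.name, dwell, sum(cost_parts.values()),
                      sum(qaly_parts.values()), cost_parts, qaly_parts)


def evaluate_cvc(arm: ArmParams, extras: CvcExtras, dwell: float | str = FULL) -> ArmOutcome:
    """Expected outcome of the composite CVC arm (dwell-invariant).

    Cost: mean_insertions x (insertion + per-episode maintenance + removal)
    plus a once-per-course expected complication cost. QALYs: catheter time
    (mean_insertions x median episode survival, at the complication-weighted
    utility) plus intermission time (n_intermissions x duration, at the
    intermission utility).
    """
    comp = expected_complication_cost(arm)
    k = extras.mean_insertions
    cost_parts = {
        "insertion": k * arm.insertion.mean,
        "maintenance": k * arm.maintenance.mean,
        "removal": k * arm.removal.mean,
        "complication": comp,
    }
    qaly_parts = {
        "on_catheter": k * arm.survival.median * weighted_utility(arm),
        "intermission": extras.n_intermissions * extras.intermission_duration
        * extras.intermission_utility,
    }
    return ArmOutcome(arm.name, dwell, sum(cost_parts.values()),
                      sum(qaly_parts.values()), cost_parts, qaly_parts)


def evaluate_arm(params: ModelParameters, arm: str, dwell: float | str = FULL) -> ArmOutcome:
    """Evaluate one arm of the model at a dwell scenario (years or FULL)."""
    d = dwell_years(dwell, params)
    if arm == "CVC":
        out = evaluate_cvc(params.arms["CVC"], params.cvc_extras, d)
    else:
        out = evaluate_simple_arm(params.arms[arm], d)
    out.dwell = dwell
    return out


def scenario_table(params: ModelParameters,
                   dwells: Sequence[float | str] = ("6m", "12m", FULL)) -> list[ArmOutcome]:
    """Evaluate all three arms over a list of dwell scenarios."""
    dwells = list(dwells)
    if not dwells:
        raise ValueError("dwells must be nonempty")
    return [evaluate_arm(params, arm, d) for d in dwells for arm in params.arms]


def outcomes_frame(outcomes: Iterable[ArmOutcome]) -> pd.DataFrame:
    """Tidy DataFrame of outcomes (one row per arm x dwell)."""
    rows = []
    for o in outcomes:
        row = {"arm": o.arm, "dwell": o.dwell,
               "cost": o.expected_cost, "qaly": o.expected_qaly}
        row.update({f"cost_{k}": v for k, v in o.cost_components.items()})
        rows.append(row)
    return pd.DataFrame(rows)
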