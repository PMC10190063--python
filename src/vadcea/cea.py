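"""Cost-effectiveness algebra: CER, pairwise ICER with dominance, and the
willingness-to-pay recommendation via net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .tree import ArmOutcome

__all__ = ["CEAComparison", "cer", "icer", "nmb", "recommend", "cea_table"]


@dataclass
class CEAComparison:
    """Pairwise incremental comparison of two arm outcomes.

    ``icer`` is defined only when the cost and QALY increments share a sign
    (otherwise one arm dominates: cheaper and more effective). Identical
    outcomes yield the ``undefined`` flag rather than a ratio.
    """

    pair: tuple[str, str]
    delta_cost: float
    delta_qaly: float
    icer: float | None = None
    dominance: str | None = None  # 'arm1-dominant' | 'arm2-dominant' | 'undefined'


def cer(outcome: ArmOutcome) -> float:
    """Cost-effectiveness ratio: cost per QALY of a single strategy."""
    if outcome.expected_qaly <= 0:
        raise ZeroDivisionError(f"{outcome.arm}: QALY must be > 0 for a CER")
    return outcome.expected_cost / outcome.expected_qaly


def icer(a: ArmOutcome, b: ArmOutcome) -> CEAComparison:
    """Incremental cost-effectiveness of ``a`` versus ``b``."""
    dc = a.expected_cost - b.expected_cost
    dq = a.expected_qaly - b.expected_qaly
    comp = CEAComparison(pair=(a.arm, b.arm), delta_cost=dc, delta_qaly=dq)
    if dq == 0.0 and dc == 0.0:
        comp.dominance = "undefined"
    elif dq == 0.0:
        comp.dominance = "arm1-dominant" if dc < 0 else "arm2-dominant"
    elif (dc >= 0) == (dq > 0) and dc != 0.0:
        comp.icer = dc / dq
    elif dc <= 0 and dq > 0:
        comp.dominance = "arm1-dominant"
    else:
        comp.dominance = "arm2-dominant"
    return comp


def nmb(outcome: ArmOutcome, wtp: float) -> float:
    """Net monetary benefit: wtp * QALY - cost."""
    return wtp * outcome.expected_qaly - outcome.expected_cost


def recommend(outcomes: Sequence[ArmOutcome], wtp: float) -> str:
    """The arm maximizing net monetary benefit at ``wtp`` (ties -> cheaper).

    Equivalent on non-dominated frontiers to walking the ICER ladder and
    accepting steps whose ICER falls below the willingness to pay.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes to recommend")
    best = max(outcomes, key=lambda o: (nmb(o, wtp), -o.expected_cost))
    return best.arm


def cea_table(outcomes: Sequence[ArmOutcome], wtp: float | None = None) -> pd.DataFrame:
    """Table of cost, QALY, CER and pairwise ICERs per dwell scenario.

    For each dwell the arms are compared pairwise against every strictly
    less effective arm (one column per comparator), mirroring the usual
    presentation of a three-strategy cost-utility analysis.
    """
    rows = []
    by_dwell: dict = {}
    for o in outcomes:
        by_dwell.setdefault(o.dwell, []).append(o)
    for dwell, outs in by_dwell.items():
        for o in outs:
            row = {"arm": o.arm, "dwell": dwell, "cost": o.expected_cost,
                   "qaly": o.expected_qaly, "cer": cer(o)}
            for other in outs:
                if other.arm == o.arm:
                    continue
                comp = icer(o, other)
                if o.expected_qaly > other.expected_qaly:
                    row[f"icer_vs_{other.arm}"] = (
                        comp.icer if comp.icer is not None else comp.dominance)
            if wtp is not None:
                row["nmb"] = nmb(o, wtp)
            rows.append(row)
    return pd.DataFrame(rows)
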