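"""Model/Results facade over the decision-tree cost-utility analysis.

``VenousAccessCUA`` wraps a parameter set (packaged base case, a config
file, or parameters estimated from a matched patient-level cohort);
``fit()`` evaluates the decision tree over the dwell-time scenarios and
returns a ``CUAResults`` carrying the arm outcomes, the cost-utility table
with pairwise ICERs, and the sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import cea, sensitivity, tree
from .estimation import estimate_parameters
from .parameters import ModelParameters, default_parameters, load_parameters
from .tree import FULL, ArmOutcome

__all__ = ["VenousAccessCUA", "CUAResults"]


class VenousAccessCUA:
    """Three-arm decision-tree cost-utility model (CVC vs PICC vs IVAP)."""

    def __init__(self, params: ModelParameters | None = None):
        self.params = params if params is not None else default_parameters()

    @classmethod
    def from_config(cls, path) -> "VenousAccessCUA":
        """Build from a JSON/YAML parameter config."""
        return cls(load_parameters(path))

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    base: ModelParameters | None = None) -> "VenousAccessCUA":
        """Build by estimating parameters from a (matched) cohort table."""
        return cls(estimate_parameters(cohort, base=base))

    def fit(self, dwells: Sequence = ("6m", "12m", FULL)) -> "CUAResults":
        """Evaluate expected cost and QALYs per arm per dwell scenario."""
        outcomes = tree.scenario_table(self.params, dwells)
        return CUAResults(model=self, outcomes=outcomes, dwells=tuple(dwells))


@dataclass
class CUAResults:
    """Evaluated decision-tree outcomes plus cost-utility comparisons."""

    model: VenousAccessCUA
    outcomes: list[ArmOutcome]
    dwells: tuple

    @property
    def params(self) -> ModelParameters:
        return self.model.params

    def outcome(self, arm: str, dwell=FULL) -> ArmOutcome:
        for o in self.outcomes:
            if o.arm == arm and o.dwell == dwell:
                return o
        raise KeyError(f"no outcome for {arm!r} at dwell {dwell!r}")

    @property
    def table(self) -> pd.DataFrame:
        """Cost / QALY / CER / pairwise-ICER table (one row per arm x dwell)."""
        return cea.cea_table(self.outcomes, wtp=self.params.wtp)

    def recommend(self, wtp: float | None = None, dwell=FULL) -> str:
        """Arm maximizing net monetary benefit at the threshold."""
        wtp = wtp if wtp is not None else self.params.wtp
        outs = [o for o in self.outcomes if o.dwell == dwell]
        return cea.recommend(outs, wtp)

    def dsa(self, pair: tuple[str, str] = ("IVAP", "CVC"), keys=None,
            dwell=FULL) -> list[sensitivity.TornadoEntry]:
        """One-way tornado of the pairwise ICER."""
        return sensitivity.one_way_dsa(self.params, pair=pair, keys=keys, dwell=dwell)

    def psa(self, n: int = 1000, seed: int | None = 0,
            dwell=FULL) -> sensitivity.PSADraws:
        """Probabilistic sensitivity analysis draws."""
        return sensitivity.sample_psa(self.params, n=n, seed=seed, dwell=dwell)

    def summary(self) -> str:
        """Human-readable cost-utility summary."""
        lines = ["Venous-access cost-utility analysis (decision tree)",
                 "=" * 56]
        tab = self.table
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda v: f"{v:,.2f}"):
            for dwell in self.dwells:
                lines.append(f"\nDwell scenario: {dwell}")
                sub = tab[tab["dwell"] == dwell].drop(columns=["dwell"])
                lines.append(sub.to_string(index=False))
        wtp = self.params.wtp
        lines.append(f"\nWillingness to pay: {wtp:,.2f} USD/QALY")
        lines.append(f"Recommended arm (max net monetary benefit): {self.recommend()}")
        return "\n".join(lines)
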