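"""Model parameters for the venous-access cost-utility model.

The decision model compares three venous access devices used for long-term
breast-cancer chemotherapy: central venous catheters (CVC), peripherally
inserted central catheters (PICC) and implantable venous access ports (IVAP).
Each arm is described by itemized costs (insertion, maintenance, removal,
per-type complication treatment), a complication probability with a
per-type constituent mix, a health-utility pair (with / without
complication) and a parametric catheter-survival specification whose median
drives maintenance-visit counts and quality-adjusted life years.

This module holds the typed parameter containers, the packaged base-case
values, config-file round-tripping (JSON / YAML), a stable string key for
every parameter eligible for sensitivity analysis, and the conversion of
(mean, SD / 95% CI) specifications into sampling distributions for the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ARM_NAMES",
    "DSA_KEYS",
    "CostParam",
    "UtilityParam",
    "ComplicationProfile",
    "SurvivalSpec",
    "ArmParams",
    "CvcExtras",
    "ModelParameters",
    "SamplingDistribution",
    "SchemaError",
    "ValidationError",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "derive_sampling_distribution",
]

ARM_NAMES = ("CVC", "PICC", "IVAP")

#: 95% CI halfwidth in SD units (normal approximation).
_Z95 = 3.92


class SchemaError(KeyError):
    """A config file is missing a required parameter or field."""


class ValidationError(ValueError):
    """A parameter value violates its domain constraints."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CostParam:
    """A cost input in USD: point mean plus optional dispersion.

    ``sd`` is the patient-level dispersion (used when simulating itemized
    patient costs); ``ci`` is the printed 95% interval of the *mean*, whose
    halfwidth / 1.96 is the standard error used for parameter uncertainty.
    When only an interval is given and it is a patient-level 95% range
    rather than a CI of the mean (the per-visit maintenance costs, whose
    intervals span nearly +/-100% of the mean), ``n`` carries the sample
    size behind the mean so the SE can be recovered as range-SD / sqrt(n).
    """

    mean: float
    sd: float | None = None
    ci: tuple[float, float] | None = None
    label: str = ""
    n: int | None = None

    def validate(self) -> None:
        if not self.mean > 0:
            raise ValidationError(f"{self.label or 'cost'}: mean must be > 0, got {self.mean}")
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.label}: sd must be >= 0")
        if self.ci is not None:
            lo, hi = self.ci
            if not lo < hi:
                raise ValidationError(f"{self.label}: ci_low must be < ci_high")
            if self.sd is not None and not (lo < self.mean < hi):
                raise ValidationError(f"{self.label}: mean outside its CI")

    @property
    def se(self) -> float:
        """Standard error of the mean: CI-based when a CI is printed."""
        if self.ci is not None:
            half = (self.ci[1] - self.ci[0]) / _Z95
            if self.sd is None and self.n:
                return half / math.sqrt(self.n)  # interval was a patient-level range
            return half
        if self.sd is not None:
            return self.sd
        return 0.1 * self.mean

    @property
    def patient_sd(self) -> float:
        """Patient-level SD for cohort simulation (printed SD preferred)."""
        if self.sd is not None:
            return self.sd
        if self.ci is not None:
            return (self.ci[1] - self.ci[0]) / _Z95
        return 0.1 * self.mean


@dataclass
class UtilityParam:
    """A health-utility weight in [0, 1]."""

    mean: float
    sd: float | None = None
    ci: tuple[float, float] | None = None
    label: str = ""

    def validate(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValidationError(f"{self.label or 'utility'}: mean must lie in [0,1], got {self.mean}")
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.label}: sd must be >= 0")

    @property
    def se(self) -> float:
        if self.ci is not None:
            return (self.ci[1] - self.ci[0]) / _Z95
        if self.sd is not None:
            return self.sd
        return 0.1 * self.mean


@dataclass
class ComplicationProfile:
    """Complication incidence and its per-type constituent mix for one arm.

    ``probability`` is the share of patients with at least one complication;
    ``counts`` are the observed per-type event counts from which ``mix``
    (constituent ratios) derives; ``type_costs`` maps each type in the mix
    to its treatment-cost parameter.
    """

    probability: float
    n_events: int | None = None
    n_patients: int | None = None
    counts: dict[str, int] = field(default_factory=dict)
    mix: dict[str, float] = field(default_factory=dict)
    type_costs: dict[str, CostParam] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"complication probability must lie in [0,1], got {self.probability}")
        if self.mix:
            total = sum(self.mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"complication mix must sum to 1, sums to {total}")
            missing = set(self.mix) - set(self.type_costs)
            if missing:
                raise ValidationError(f"complication types lacking a cost: {sorted(missing)}")
        if self.n_events is not None and self.n_patients:
            implied = self.n_events / self.n_patients
            if abs(implied - self.probability) > 5e-4:  # printed probabilities are rounded to 4 dp
                raise ValidationError(
                    f"probability {self.probability} inconsistent with counts "
                    f"{self.n_events}/{self.n_patients} = {implied:.6f}"
                )


@dataclass
class SurvivalSpec:
    """Catheter survival: median dwell time (years) plus parametric family.

    ``fitted_params`` carries family-specific parameters when known — for the
    generator and PSA the lognormal needs ``sigma`` and the Gompertz needs
    ``shape`` (the rate is solved from the median).
    """

    median: float
    family: str = "gompertz"
    fitted_params: dict[str, float] = field(default_factory=dict)

    _FAMILIES = ("lognormal", "gompertz", "weibull", "exponential")

    def validate(self) -> None:
        if not self.median > 0:
            raise ValidationError(f"median survival must be > 0, got {self.median}")
        if self.family not in self._FAMILIES:
            raise ValidationError(f"unknown survival family {self.family!r}")


@dataclass
class ArmParams:
    """Everything the decision tree needs about one device arm.

    ``maintenance`` is per visit for PICC/IVAP and per insertion episode for
    CVC (whose dwell is too short for scheduled visits; its maintenance is
    billed per catheterization). ``maintenance_interval`` is the scheduled
    time between visits in years (absent for CVC).
    """

    name: str
    insertion: CostParam
    maintenance: CostParam
    removal: CostParam
    complications: ComplicationProfile
    utility: UtilityParam
    utility_with_complication: UtilityParam
    survival: SurvivalSpec
    maintenance_interval: float | None = None

    def validate(self) -> None:
        if self.name not in ARM_NAMES:
            raise ValidationError(f"unknown arm name {self.name!r}")
        for cp in (self.insertion, self.maintenance, self.removal):
            cp.validate()
        self.complications.validate()
        self.utility.validate()
        self.utility_with_complication.validate()
        self.survival.validate()
        if self.maintenance_interval is not None and not self.maintenance_interval > 0:
            raise ValidationError(f"{self.name}: maintenance_interval must be > 0")


@dataclass
class CvcExtras:
    """CVC multi-catheterization cycle: a CVC is removed after each
    chemotherapy cycle and reinserted after an intermission, so the arm is a
    composite of ``mean_insertions`` catheter episodes separated by
    ``n_intermissions`` intermissions of ``intermission_duration`` years
    lived at ``intermission_utility``."""

    mean_insertions: float
    n_intermissions: float
    intermission_duration: float
    intermission_utility: float
    intermission_duration_param: CostParam | None = None  # carries SE/CI for sampling
    mean_insertions_param: CostParam | None = None
    n_intermissions_param: CostParam | None = None

    def validate(self, check_tie: bool = True) -> None:
        for name, v in (
            ("mean_insertions", self.mean_insertions),
            ("n_intermissions", self.n_intermissions),
            ("intermission_duration", self.intermission_duration),
            ("intermission_utility", self.intermission_utility),
        ):
            if not v > 0:
                raise ValidationError(f"cvc_extras.{name} must be > 0, got {v}")
        if check_tie and abs(self.n_intermissions - (self.mean_insertions - 1.0)) > 1e-6:
            raise ValidationError(
                "cvc_extras: n_intermissions must equal mean_insertions - 1 "
                f"({self.n_intermissions} vs {self.mean_insertions - 1})"
            )


@dataclass
class ModelParameters:
    """The full parameter set of the three-arm decision model."""

    arms: dict[str, ArmParams]
    cvc_extras: CvcExtras
    wtp: float = 34794.8108
    currency_rate: float = 6.9838  # RMB per USD, metadata only
    days_per_month: float = 30.0
    days_per_year: float = 365.0

    def validate(self, check_cvc_tie: bool = True) -> None:
        if tuple(sorted(self.arms)) != tuple(sorted(ARM_NAMES)):
            raise ValidationError(f"expected arms {ARM_NAMES}, got {tuple(self.arms)}")
        for arm in self.arms.values():
            arm.validate()
        self.cvc_extras.validate(check_tie=check_cvc_tie)

    # -- stable-key access (needed by the sensitivity module) ---------------

    def keys(self) -> tuple[str, ...]:
        """All parameter keys eligible for one-way / probabilistic SA."""
        return DSA_KEYS

    def get_value(self, key: str) -> float:
        """Point value (mean / probability / median) behind a stable key."""
        return _accessor(key)[0](self)

    def with_value(self, key: str, value: float) -> "ModelParameters":
        """A deep copy with one keyed value replaced (no cross-field
        revalidation: sensitivity analyses perturb keys independently)."""
        out = copy.deepcopy(self)
        _accessor(key)[1](out, value)
        return out

    def spec_for(self, key: str):
        """The underlying parameter object (CostParam/UtilityParam/...)."""
        return _accessor(key)[2](self)


# ---------------------------------------------------------------------------
# packaged base-case values
# ---------------------------------------------------------------------------

# key -> (mean, sd, ci_low, ci_high, distribution)
_BASE_TABLE: dict[str, tuple] = {
    "c1_CVC_insertion": (68.0747, 43.2521, 66.7348, 69.4147, "gamma"),
    "c1_CVC_maintenance": (41.9615, 45.6716, 40.4214, 43.5015, "gamma"),
    "c1_CVC_removal": (8.2753, 3.3928, 8.1466, 8.4041, "gamma"),
    "c2_PICC_insertion": (349.5522, 102.7811, 329.5638, 369.5405, "gamma"),
    "c2_PICC_perMaintenance": (21.6773, None, 0.433, 42.9217, "gamma"),
    "c2_PICC_removal": (7.2909, 3.4561, 6.7812, 7.8007, "gamma"),
    "c3_IVAP_insertion": (844.8203, 317.5976, 828.9301, 860.7106, "gamma"),
    "c3_IVAP_perMaintenance": (32.1395, None, 0.6413, 63.6376, "gamma"),
    "c3_IVAP_removal": (82.3272, 6.8959, 81.5174, 83.137, "gamma"),
    "c_complication_allergy": (30.7898, 52.408, -13.0244, 74.604, "gamma"),
    "c_complication_CatheterRupture": (44.1021, None, 35.2817, 52.9225, "gamma"),
    "c_complication_CRBSI": (47.1949, None, 37.7559, 56.6339, "gamma"),
    "c_complication_drugExtravasation": (25.5226, 0.3675, 22.2205, 28.8248, "gamma"),
    "c_complication_exudation": (28.8435, 23.8289, 11.7973, 45.8896, "gamma"),
    "c_complication_infection": (131.2002, 196.0126, -50.0812, 312.4816, "gamma"),
    "c_complication_Nslippage": (2.2624, None, 1.8099, 2.7149, "gamma"),
    "c_complication_occlusion": (38.6511, 36.5992, 19.8335, 57.4687, "gamma"),
    "c_complication_Pslippage": (152.7048, 61.313, 0.3948, 305.0149, "gamma"),
    "c_complication_skinDamage": (14.2501, 3.7543, -19.4812, 47.9815, "gamma"),
    "c_complication_thrombosis": (17.0416, 19.8661, -3.8066, 37.8898, "gamma"),
    "c_complication_Tslippage": (3.8460, 2.1042, -1.381, 9.0731, "gamma"),
    "CVC_intermission": (0.0686, 0.1772, 0.06174, 0.07546, "normal"),
    "CVC_mean_insertionTimes": (4.5589, 2.8271, 4.416248, 4.701477, "normal"),
    "CVC_intervals": (3.5589, 2.8271, 3.416348, 3.701477, "normal"),
    "p1_CVC_complication": (0.0734, None, None, None, "beta"),
    "p2_PICC_complication": (0.0728, None, None, None, "beta"),
    "p3_IVAP_complication": (0.0384, None, None, None, "beta"),
    "T1_CVC_medianSurvivalTime": (0.01096, None, None, None, "lognormal"),
    "T2_PICC_maintenanceInterval": (0.0192, None, None, None, None),
    "T2_PICC_medianSurvivalTime": (0.4137, None, None, None, "gompertz"),
    "T3_IVAP_maintenanceInterval": (0.0822, None, None, None, None),
    "T3_IVAP_medianSurvivalTime": (2.8493, None, None, None, "gompertz"),
    "u1_CVC": (0.8989706, 0.0644212, 0.8753407, 0.9226005, "beta"),
    "u1_CVC_complication": (0.8778395, 0.0228473, None, None, "beta"),
    "u1_CVC_intermission": (0.814, None, None, None, "beta"),
    "u2_PICC": (0.8806194, 0.0565468, 0.8602321, 0.9010067, "beta"),
    "u2_PICC_complication": (0.862279, 0.0614081, 0.8054858, 0.9190719, "beta"),
    "u3_IVAP": (0.9448492, 0.0726747, 0.9340994, 0.955599, "beta"),
    "u3_IVAP_complication": (0.942318, None, None, None, "beta"),
}

#: Parameters entering one-way and probabilistic sensitivity analyses
#: (every base-table row with an assigned distribution; the two fixed
#: maintenance intervals are excluded).
DSA_KEYS: tuple[str, ...] = tuple(k for k, v in _BASE_TABLE.items() if v[4] is not None)

# observed complication counts per arm: type -> count
_COMPLICATION_COUNTS = {
    "CVC": {
        "Pslippage": 13, "infection": 3, "exudation": 27, "occlusion": 16,
        "CRBSI": 1, "thrombosis": 9, "allergy": 7, "skinDamage": 19,
        "Tslippage": 16,
    },
    "PICC": {
        "Pslippage": 7, "infection": 6, "exudation": 14, "occlusion": 3,
        "thrombosis": 8, "allergy": 8, "skinDamage": 7, "CatheterRupture": 2,
    },
    "IVAP": {
        "infection": 10, "exudation": 1, "occlusion": 34, "thrombosis": 8,
        "allergy": 1, "drugExtravasation": 3, "Nslippage": 1,
    },
}

_ARM_SIZES = {"CVC": 1512, "PICC": 756, "IVAP": 1512}

# generator-side parametric survival shapes (see docs/methods.md)
_SURVIVAL_SHAPES = {
    "CVC": {"sigma": 0.5},
    "PICC": {"shape": 2.0},
    "IVAP": {"shape": 0.7},
}


def _cost(key: str, entry) -> CostParam:
    mean, sd, lo, hi, _ = entry
    ci = (lo, hi) if lo is not None else None
    return CostParam(mean=mean, sd=sd, ci=ci, label=key)


def _utility(key: str, entry) -> UtilityParam:
    mean, sd, lo, hi, _ = entry
    ci = (lo, hi) if lo is not None else None
    return UtilityParam(mean=mean, sd=sd, ci=ci, label=key)


def _build_parameters(table: Mapping[str, tuple],
                      counts: Mapping[str, Mapping[str, int]],
                      arm_sizes: Mapping[str, int],
                      settings: Mapping[str, float] | None = None) -> ModelParameters:
    def cost(key):
        return _cost(key, table[key])

    def util(key):
        return _utility(key, table[key])

    type_costs = {
        t: cost(f"c_complication_{t}")
        for t in sorted({t for arm in counts.values() for t in arm})
    }

    def profile(arm, pkey):
        c = dict(counts[arm])
        total = sum(c.values())
        mix = {t: n / total for t, n in c.items()}
        return ComplicationProfile(
            probability=table[pkey][0],
            n_events=total,
            n_patients=arm_sizes.get(arm),
            counts=c,
            mix=mix,
            type_costs={t: type_costs[t] for t in c},
        )

    arms = {
        "CVC": ArmParams(
            name="CVC",
            insertion=cost("c1_CVC_insertion"),
            maintenance=cost("c1_CVC_maintenance"),
            removal=cost("c1_CVC_removal"),
            complications=profile("CVC", "p1_CVC_complication"),
            utility=util("u1_CVC"),
            utility_with_complication=util("u1_CVC_complication"),
            survival=SurvivalSpec(
                median=table["T1_CVC_medianSurvivalTime"][0],
                family="lognormal",
                fitted_params=dict(_SURVIVAL_SHAPES["CVC"]),
            ),
        ),
        "PICC": ArmParams(
            name="PICC",
            insertion=cost("c2_PICC_insertion"),
            maintenance=cost("c2_PICC_perMaintenance"),
            removal=cost("c2_PICC_removal"),
            complications=profile("PICC", "p2_PICC_complication"),
            utility=util("u2_PICC"),
            utility_with_complication=util("u2_PICC_complication"),
            survival=SurvivalSpec(
                median=table["T2_PICC_medianSurvivalTime"][0],
                family="gompertz",
                fitted_params=dict(_SURVIVAL_SHAPES["PICC"]),
            ),
            maintenance_interval=table["T2_PICC_maintenanceInterval"][0],
        ),
        "IVAP": ArmParams(
            name="IVAP",
            insertion=cost("c3_IVAP_insertion"),
            maintenance=cost("c3_IVAP_perMaintenance"),
            removal=cost("c3_IVAP_removal"),
            complications=profile("IVAP", "p3_IVAP_complication"),
            utility=util("u3_IVAP"),
            utility_with_complication=util("u3_IVAP_complication"),
            survival=SurvivalSpec(
                median=table["T3_IVAP_medianSurvivalTime"][0],
                family="gompertz",
                fitted_params=dict(_SURVIVAL_SHAPES["IVAP"]),
            ),
            maintenance_interval=table["T3_IVAP_maintenanceInterval"][0],
        ),
    }

    # per-visit maintenance intervals are patient-level ranges; attach the
    # arm size so their SE (range-SD / sqrt(n)) can be derived
    for a in ("PICC", "IVAP"):
        arms[a].maintenance.n = arm_sizes.get(a)

    extras = CvcExtras(
        mean_insertions=table["CVC_mean_insertionTimes"][0],
        n_intermissions=table["CVC_intervals"][0],
        intermission_duration=table["CVC_intermission"][0],
        intermission_utility=table["u1_CVC_intermission"][0],
        intermission_duration_param=cost("CVC_intermission"),
        mean_insertions_param=cost("CVC_mean_insertionTimes"),
        n_intermissions_param=cost("CVC_intervals"),
    )

    settings = dict(settings or {})
    return ModelParameters(arms=arms, cvc_extras=extras, **settings)


def default_parameters() -> ModelParameters:
    """The packaged base-case parameter set for the three arms."""
    p = _build_parameters(_BASE_TABLE, _COMPLICATION_COUNTS, _ARM_SIZES)
    p.validate()
    return p


# ---------------------------------------------------------------------------
# stable-key accessors
# ---------------------------------------------------------------------------

_ARM_OF_PREFIX = {"c1": "CVC", "c2": "PICC", "c3": "IVAP",
                  "p1": "CVC", "p2": "PICC", "p3": "IVAP",
                  "u1": "CVC", "u2": "PICC", "u3": "IVAP",
                  "T1": "CVC", "T2": "PICC", "T3": "IVAP"}

_COMPONENT_ALIASES = {"insertion": "insertion", "maintenance": "maintenance",
                      "perMaintenance": "maintenance", "removal": "removal"}


def _accessor(key: str):
    """(getter, setter, spec-getter) triple for a stable parameter key."""
    if key not in _BASE_TABLE:
        raise KeyError(f"unknown parameter key {key!r}")

    if key.startswith("c_complication_"):
        t = key[len("c_complication_"):]

        def get(p):
            for arm in p.arms.values():
                if t in arm.complications.type_costs:
                    return arm.complications.type_costs[t].mean
            raise KeyError(key)

        def setv(p, v):
            for arm in p.arms.values():
                if t in arm.complications.type_costs:
                    arm.complications.type_costs[t].mean = v

        def spec(p):
            for arm in p.arms.values():
                if t in arm.complications.type_costs:
                    return arm.complications.type_costs[t]
            raise KeyError(key)

        return get, setv, spec

    prefix = key.split("_", 1)[0]
    if prefix in ("c1", "c2", "c3"):
        arm = _ARM_OF_PREFIX[prefix]
        comp = _COMPONENT_ALIASES[key.split("_")[-1]]
        return (
            lambda p: getattr(p.arms[arm], comp).mean,
            lambda p, v: setattr(getattr(p.arms[arm], comp), "mean", v),
            lambda p: getattr(p.arms[arm], comp),
        )
    if prefix in ("p1", "p2", "p3"):
        arm = _ARM_OF_PREFIX[prefix]
        return (
            lambda p: p.arms[arm].complications.probability,
            lambda p, v: setattr(p.arms[arm].complications, "probability", v),
            lambda p: p.arms[arm].complications,
        )
    if key.endswith("medianSurvivalTime"):
        arm = _ARM_OF_PREFIX[prefix]
        return (
            lambda p: p.arms[arm].survival.median,
            lambda p, v: setattr(p.arms[arm].survival, "median", v),
            lambda p: p.arms[arm].survival,
        )
    if key.endswith("maintenanceInterval"):
        arm = _ARM_OF_PREFIX[prefix]
        return (
            lambda p: p.arms[arm].maintenance_interval,
            lambda p, v: setattr(p.arms[arm], "maintenance_interval", v),
            lambda p: p.arms[arm],
        )
    if prefix in ("u1", "u2", "u3"):
        arm = _ARM_OF_PREFIX[prefix]
        if key == "u1_CVC_intermission":
            return (
                lambda p: p.cvc_extras.intermission_utility,
                lambda p, v: setattr(p.cvc_extras, "intermission_utility", v),
                lambda p: UtilityParam(mean=p.cvc_extras.intermission_utility, label=key),
            )
        attr = "utility_with_complication" if key.endswith("_complication") else "utility"
        return (
            lambda p: getattr(p.arms[arm], attr).mean,
            lambda p, v: setattr(getattr(p.arms[arm], attr), "mean", v),
            lambda p: getattr(p.arms[arm], attr),
        )
    if key == "CVC_intermission":
        def setd(p, v):
            p.cvc_extras.intermission_duration = v
            if p.cvc_extras.intermission_duration_param is not None:
                p.cvc_extras.intermission_duration_param.mean = v
        return (lambda p: p.cvc_extras.intermission_duration, setd,
                lambda p: p.cvc_extras.intermission_duration_param)
    if key == "CVC_mean_insertionTimes":
        def setm(p, v):
            p.cvc_extras.mean_insertions = v
            if p.cvc_extras.mean_insertions_param is not None:
                p.cvc_extras.mean_insertions_param.mean = v
        return (lambda p: p.cvc_extras.mean_insertions, setm,
                lambda p: p.cvc_extras.mean_insertions_param)
    if key == "CVC_intervals":
        def setn(p, v):
            p.cvc_extras.n_intermissions = v
            if p.cvc_extras.n_intermissions_param is not None:
                p.cvc_extras.n_intermissions_param.mean = v
        return (lambda p: p.cvc_extras.n_intermissions, setn,
                lambda p: p.cvc_extras.n_intermissions_param)
    raise KeyError(f"unknown parameter key {key!r}")  # pragma: no cover


def assigned_distribution(key: str) -> str | None:
    """The PSA distribution family assigned to a parameter key."""
    return _BASE_TABLE[key][4]


def dsa_bounds(params: ModelParameters, key: str) -> tuple[float, float]:
    """Low/high excursion for one-way sensitivity analysis: the printed 95%
    CI when available, otherwise +/-10% of the base value; clipped to the
    parameter's support (costs/times >= 0, utilities/probabilities in [0,1],
    CVC insertions >= 1)."""
    v = params.get_value(key)
    spec = params.spec_for(key)
    ci = getattr(spec, "ci", None)
    if ci is not None:
        lo, hi = ci
    else:
        lo, hi = 0.9 * v, 1.1 * v
    if key.startswith(("u", "p")):
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    else:
        lo = max(lo, 0.0)
    if key == "CVC_mean_insertionTimes":
        lo = max(lo, 1.0)
    return lo, hi


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("mean",)


def _to_config(params: ModelParameters) -> dict:
    table = {}
    for key, entry in _BASE_TABLE.items():
        spec = params.spec_for(key)
        mean = params.get_value(key)
        row: dict = {"mean": mean}
        sd = getattr(spec, "sd", None)
        ci = getattr(spec, "ci", None)
        if sd is not None:
            row["sd"] = sd
        if ci is not None:
            row["ci_low"], row["ci_high"] = ci
        dist = entry[4]
        if dist is not None:
            row["distribution"] = dist
        if key.endswith("medianSurvivalTime"):
            arm = _ARM_OF_PREFIX[key.split("_", 1)[0]]
            row.update(params.arms[arm].survival.fitted_params)
            row["family"] = params.arms[arm].survival.family
        table[key] = row
    return {
        "parameters": table,
        "complication_counts": {a: dict(p.complications.counts) for a, p in params.arms.items()},
        "arm_sizes": {a: p.complications.n_patients for a, p in params.arms.items()},
        "settings": {
            "wtp": params.wtp,
            "currency_rate": params.currency_rate,
            "days_per_month": params.days_per_month,
            "days_per_year": params.days_per_year,
        },
    }


def _from_config(cfg: Mapping) -> ModelParameters:
    if "parameters" not in cfg:
        raise SchemaError("config lacks a 'parameters' section")
    raw = dict(cfg["parameters"])
    # the one key whose printed label contains a space
    if "CVC intervals" in raw:
        raw["CVC_intervals"] = raw.pop("CVC intervals")
    table = {}
    for key, entry in _BASE_TABLE.items():
        if key not in raw:
            raise SchemaError(f"config missing parameter {key!r}")
        row = raw[key]
        for f in _REQUIRED_FIELDS:
            if f not in row:
                raise SchemaError(f"parameter {key!r} missing field {f!r}")
        lo, hi = row.get("ci_low"), row.get("ci_high")
        if (lo is None) != (hi is None):
            raise SchemaError(f"parameter {key!r} must give both or neither CI bound")
        table[key] = (row["mean"], row.get("sd"), lo, hi,
                      row.get("distribution", entry[4]))
    counts = cfg.get("complication_counts", _COMPLICATION_COUNTS)
    arm_sizes = cfg.get("arm_sizes", _ARM_SIZES)
    settings = cfg.get("settings", {})
    params = _build_parameters(table, counts, arm_sizes, settings)
    for arm, spec in _SURVIVAL_SHAPES.items():
        key = {"CVC": "T1_CVC_medianSurvivalTime",
               "PICC": "T2_PICC_medianSurvivalTime",
               "IVAP": "T3_IVAP_medianSurvivalTime"}[arm]
        row = raw[key]
        extra = {k: row[k] for k in ("sigma", "shape") if k in row}
        if extra:
            params.arms[arm].survival.fitted_params = extra
        if "family" in row:
            params.arms[arm].survival.family = row["family"]
    params.validate()
    return params


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize to JSON or YAML (chosen by file suffix)."""
    path = Path(path)
    cfg = _to_config(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .json/.yaml)")


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter config (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .json/.yaml)")
    return _from_config(cfg)


# ---------------------------------------------------------------------------
# sampling distributions
# ---------------------------------------------------------------------------


@dataclass
class SamplingDistribution:
    """A concrete sampling rule for one parameter, moment-matched to its
    target mean (and SD where the family permits)."""

    family: str
    params: dict[str, float]
    target_mean: float

    def rvs(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        p = self.params
        if self.family == "point":
            return np.full(size, self.target_mean) if size else self.target_mean
        if self.family == "gamma":
            return rng.gamma(p["shape"], 1.0 / p["rate"], size)
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size)
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size)
        if self.family == "truncated-normal":
            a = (p["lower"] - p["loc"]) / p["scale"]
            u = rng.uniform(stats.norm.cdf(a), 1.0, size)
            return p["loc"] + p["scale"] * stats.norm.ppf(u)
        if self.family == "lognormal-median":
            return rng.lognormal(p["mu"], p["sigma"], size)
        if self.family == "gompertz-median":
            a, b0, cv = p["shape"], p["rate"], p["cv"]
            lo = (0.0 - b0) / (cv * b0)
            u = rng.uniform(stats.norm.cdf(lo), 1.0, size)
            b = b0 + cv * b0 * stats.norm.ppf(u)
            return np.log1p(a * math.log(2) / b) / a
        raise ValueError(f"unknown sampling family {self.family!r}")

    def mean(self) -> float:
        """Analytic mean of the sampling rule (where closed-form)."""
        p = self.params
        if self.family == "point":
            return self.target_mean
        if self.family == "gamma":
            return p["shape"] / p["rate"]
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "normal":
            return p["loc"]
        if self.family == "truncated-normal":
            return _truncnorm_mean(p["loc"], p["scale"], p["lower"])
        if self.family == "lognormal-median":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        raise ValueError(f"no closed-form mean for {self.family!r}")


def _truncnorm_mean(loc: float, scale: float, lower: float) -> float:
    from scipy.special import erfcx

    a = (lower - loc) / scale
    # Mills-ratio hazard phi(a)/Phi(-a) via erfcx, stable for extreme a
    hazard = math.sqrt(2.0 / math.pi) / erfcx(a / math.sqrt(2.0))
    return loc + scale * hazard


def gompertz_rate_from_median(shape: float, median: float) -> float:
    """Rate b of a Gompertz hazard h(t)=b*exp(shape*t) with the given median.

    S(t) = exp(-(b/shape)(e^{shape t} - 1));  t50 = ln(1 + shape ln2 / b)/shape.
    """
    if shape <= 0 or median <= 0:
        raise ValidationError("gompertz shape and median must be > 0")
    return shape * math.log(2) / math.expm1(shape * median)


def derive_sampling_distribution(param, family: str, *,
                                 sd: float | None = None,
                                 lower: float | None = None,
                                 cv: float = 0.10) -> SamplingDistribution:
    """Moment-matched sampling distribution for a parameter.

    ``param`` may be a CostParam/UtilityParam (its ``se`` supplies the SD
    unless ``sd`` overrides it), a ComplicationProfile (beta from counts),
    or a SurvivalSpec (median sampling for the assigned family).

    Families: ``gamma`` (shape=(m/sd)^2, rate=m/sd^2), ``beta`` (method of
    moments; from event counts when a profile is given), ``normal``
    (optionally truncated at ``lower`` with the location shifted so the
    truncated mean still equals the target), ``lognormal-median`` (mean-
    matched lognormal for a median-survival parameter), ``gompertz-median``
    (rate perturbed with coefficient of variation ``cv``, median recomputed).
    An SD of zero yields a degenerate point mass.
    """
    if family == "beta" and isinstance(param, ComplicationProfile):
        e, n = param.n_events, param.n_patients
        if not e or not n:
            raise ValidationError("beta-from-counts needs n_events and n_patients")
        return SamplingDistribution("beta", {"a": float(e), "b": float(n - e)},
                                    target_mean=e / n)
    if isinstance(param, SurvivalSpec):
        m = param.median
        if family == "lognormal-median":
            sigma = math.sqrt(math.log1p(cv ** 2))
            mu = math.log(m) - 0.5 * sigma ** 2
            return SamplingDistribution("lognormal-median", {"mu": mu, "sigma": sigma},
                                        target_mean=m)
        if family == "gompertz-median":
            shape = param.fitted_params.get("shape", 1.0)
            b = gompertz_rate_from_median(shape, m)
            return SamplingDistribution("gompertz-median",
                                        {"shape": shape, "rate": b, "cv": cv},
                                        target_mean=m)
        raise ValidationError(f"family {family!r} incompatible with a survival spec")

    mean = param.mean if hasattr(param, "mean") else float(param)
    if sd is None:
        sd = param.se if hasattr(param, "se") else cv * mean
    if sd == 0:
        return SamplingDistribution("point", {}, target_mean=mean)
    if family == "gamma":
        if mean <= 0:
            raise ValidationError("gamma requires mean > 0")
        return SamplingDistribution(
            "gamma", {"shape": (mean / sd) ** 2, "rate": mean / sd ** 2}, target_mean=mean)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta requires mean in (0,1), got {mean}")
        nu = mean * (1.0 - mean) / sd ** 2 - 1.0
        if nu <= 0:
            raise ValidationError(f"beta SD {sd} infeasible for mean {mean}")
        return SamplingDistribution(
            "beta", {"a": mean * nu, "b": (1.0 - mean) * nu}, target_mean=mean)
    if family == "normal":
        if lower is None:
            return SamplingDistribution("normal", {"loc": mean, "scale": sd}, target_mean=mean)
        # shift the location so the truncated mean matches the target mean
        def gap(loc):
            return _truncnorm_mean(loc, sd, lower) - mean
        lo_b, hi_b = mean - 50 * sd, mean + 2 * sd
        loc = optimize.brentq(gap, lo_b, hi_b, xtol=1e-12)
        return SamplingDistribution(
            "truncated-normal", {"loc": loc, "scale": sd, "lower": lower}, target_mean=mean)
    raise ValidationError(f"unknown sampling family {family!r}")
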