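"""Propensity-score matching across the three device groups.

The three-group design is realized as two pairwise logistic propensity
models (PICC vs CVC, PICC vs IVAP). Each PICC patient — the smallest group
— is greedily matched without replacement to its two nearest CVC and two
nearest IVAP neighbours on the probability scale within a caliper; strata
that violate the caliper or run short of partners are dropped whole, which
yields the 1:2:2 matched shape. Balance before/after is summarized with
standardized mean differences plus ANOVA (continuous) or Pearson chi-square
(categorical) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CATEGORICAL_COVARIATES, COVARIATES

__all__ = ["MatchResult", "estimate_propensity", "match", "balance_table",
           "matched_cohort"]


@dataclass
class MatchResult:
    """Matched strata (1 reference : 2 per comparator arm)."""

    strata: list[dict]  # {"ref": id, "CVC": [id, id], "IVAP": [id, id]}
    scores: dict[str, pd.Series]  # per comparison, indexed by patient id
    caliper: float
    n_matched: dict[str, int]
    ratio: tuple[int, ...] = (1, 2, 2)

    def matched_ids(self) -> list[int]:
        out = []
        for s in self.strata:
            out.append(s["ref"])
            for arm, ids in s.items():
                if arm != "ref":
                    out.extend(ids)
        return out


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c in CATEGORICAL_COVARIATES or cohort[c].dtype == object:
            dummies = pd.get_dummies(cohort[c], prefix=c, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        else:
            X[c] = cohort[c].astype(float)
    return sm.add_constant(X, has_constant="add")


def estimate_propensity(cohort: pd.DataFrame, covariates=COVARIATES,
                        target_pair: tuple[str, str] = ("PICC", "CVC")) -> pd.Series:
    """P(membership in ``target_pair[0]``) from a logistic model.

    Fitted on the patients of the two named device groups only; returns a
    Series of scores in (0, 1) indexed like the cohort subset.
    """
    sub = cohort[cohort["device"].isin(target_pair)]
    if sub["device"].nunique() < 2:
        raise ValueError(f"need patients from both of {target_pair}")
    y = (sub["device"] == target_pair[0]).astype(float)
    X = _design_matrix(sub, covariates)
    # drop constant covariates (would make the design singular)
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    X = X[keep]
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise ValueError(f"propensity model failed ({exc}); consider removing covariates")
    scores = pd.Series(np.asarray(fit.predict(X)), index=sub.index)
    if ((scores <= 0.0) | (scores >= 1.0)).any() or not np.isfinite(fit.params).all():
        raise ValueError(
            "propensity scores degenerate at 0/1 (perfect separation); "
            "remove the offending covariate")
    return scores


def _greedy_pairs(ref_scores: np.ndarray, pool_scores: np.ndarray, k: int,
                  caliper: float, order: np.ndarray):
    """Greedy nearest-neighbour k-matching without replacement.

    Returns, per reference index, the chosen pool indices or None when the
    caliper cannot be met; processed in the given reference order.
    """
    available = np.ones(pool_scores.size, dtype=bool)
    chosen: dict[int, list[int] | None] = {}
    for i in order:
        dist = np.abs(pool_scores - ref_scores[i])
        dist[~available] = np.inf
        idx = np.argpartition(dist, min(k, dist.size) - 1)[:k] if dist.size >= k else np.array([], int)
        idx = idx[np.isfinite(dist[idx])] if idx.size else idx
        if idx.size < k or np.any(dist[idx] > caliper):
            chosen[i] = None
            continue
        available[idx] = False
        chosen[i] = list(idx)
    return chosen


def match(cohort: pd.DataFrame, covariates=COVARIATES, ratio: tuple[int, int, int] = (1, 2, 2),
          caliper: float = 0.1, seed: int | None = 0, logit_scale: bool = False,
          reference: str = "PICC") -> MatchResult:
    """1:k:k nearest-neighbour caliper matching across the three groups.

    ``ratio`` is (reference, CVC partners, IVAP partners). The caliper is
    applied on the probability scale by default; set ``logit_scale`` to
    apply it on log-odds instead. Reference patients are processed in a
    seeded random order; a stratum failing the caliper in either pairwise
    comparison is dropped whole.
    """
    comparators = [a for a in ("CVC", "IVAP") if a != reference]
    n_ref = int((cohort["device"] == reference).sum())
    if n_ref == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    rng = np.random.default_rng(seed)

    scores = {}
    pools = {}
    ref_ids = cohort.loc[cohort["device"] == reference, "id"].to_numpy()
    ref_scores = {}
    for arm in comparators:
        s = estimate_propensity(cohort, covariates, (reference, arm))
        sub = cohort.loc[s.index]
        if logit_scale:
            s = np.log(s / (1 - s))
        scores[f"{reference}_vs_{arm}"] = pd.Series(
            np.asarray(s), index=sub["id"].to_numpy())
        ref_scores[arm] = np.asarray(s[sub["device"] == reference])
        pools[arm] = (np.asarray(s[sub["device"] == arm]),
                      sub.loc[sub["device"] == arm, "id"].to_numpy())

    k_by_arm = dict(zip(comparators, ratio[1:]))
    order = rng.permutation(n_ref)
    partner_sets = {
        arm: _greedy_pairs(ref_scores[arm], pools[arm][0], k_by_arm[arm], caliper, order)
        for arm in comparators
    }

    strata = []
    for i in order:
        if any(partner_sets[arm][i] is None for arm in comparators):
            continue
        stratum = {"ref": int(ref_ids[i])}
        for arm in comparators:
            stratum[arm] = [int(pools[arm][1][j]) for j in partner_sets[arm][i]]
        strata.append(stratum)

    n_matched = {reference: len(strata)}
    for arm in comparators:
        n_matched[arm] = k_by_arm[arm] * len(strata)
    return MatchResult(strata=strata, scores=scores, caliper=caliper,
                       n_matched=n_matched, ratio=ratio)


def matched_cohort(cohort: pd.DataFrame, result: MatchResult) -> pd.DataFrame:
    """The matched subset with an added ``stratum`` column."""
    rows = []
    for s_id, s in enumerate(result.strata):
        rows.append((s["ref"], s_id))
        for arm, ids in s.items():
            if arm != "ref":
                rows.extend((i, s_id) for i in ids)
    frame = pd.DataFrame(rows, columns=["id", "stratum"])
    return cohort.merge(frame, on="id", how="inner")


def _smd_continuous(x1, x2):
    v = (np.var(x1, ddof=1) + np.var(x2, ddof=1)) / 2.0
    return 0.0 if v == 0 else (np.mean(x1) - np.mean(x2)) / np.sqrt(v)


def _smd_binary(p1, p2):
    v = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    return 0.0 if v == 0 else (p1 - p2) / np.sqrt(v)


def _max_pairwise_smd(groups: list[np.ndarray], binary: bool) -> float:
    smds = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if binary:
                smds.append(_smd_binary(np.mean(groups[i]), np.mean(groups[j])))
            else:
                smds.append(_smd_continuous(groups[i], groups[j]))
    return float(max(abs(s) for s in smds))


def balance_table(cohort_before: pd.DataFrame, cohort_after: pd.DataFrame,
                  covariates=COVARIATES) -> pd.DataFrame:
    """Per-covariate balance diagnostics before and after matching.

    Continuous covariates get a one-way ANOVA F test across the three
    groups; categorical ones a Pearson chi-square; both stages report the
    maximum absolute pairwise standardized mean difference. A covariate
    constant within a stage has SMD 0 and its test is skipped (note column).
    """
    if cohort_before.empty or cohort_after.empty:
        raise ValueError("both cohorts must be nonempty")
    rows = []
    for cov in covariates:
        row = {"covariate": cov}
        for stage, df in (("before", cohort_before), ("after", cohort_after)):
            groups = [g for _, g in df.groupby("device")[cov]]
            categorical = cov in CATEGORICAL_COVARIATES or df[cov].dtype == object
            if df[cov].nunique() <= 1:
                row[f"smd_{stage}"] = 0.0
                row[f"stat_{stage}"] = np.nan
                row[f"p_{stage}"] = np.nan
                row[f"note_{stage}"] = "constant; test skipped"
                continue
            row[f"note_{stage}"] = ""
            if categorical:
                table = pd.crosstab(df["device"], df[cov])
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                levels = sorted(df[cov].unique())
                enc = [(np.asarray(g) == levels[0]).astype(float) for g in groups]
                row[f"smd_{stage}"] = _max_pairwise_smd(enc, binary=True)
                row[f"test_{stage}"] = "chi2"
            else:
                arrs = [np.asarray(g, dtype=float) for g in groups]
                stat, p = stats.f_oneway(*arrs)
                binary = set(np.unique(df[cov])) <= {0, 1, 0.0, 1.0}
                row[f"smd_{stage}"] = _max_pairwise_smd(arrs, binary=binary)
                row[f"test_{stage}"] = "anova"
            row[f"stat_{stage}"] = float(stat)
            row[f"p_{stage}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
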