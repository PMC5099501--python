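"""The statistical battery: correlations and rank tests on plan aggregates.

All tests are two-sided.  Absent values are dropped listwise and the pair
count ``n`` is reported with every correlation.  No multiple-testing
correction is applied by default (an optional Benjamini-Hochberg column can
be requested), so p-values are directly comparable across strata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mappings import ConditionMap

logger = logging.getLogger(__name__)

#: Plan strata analyzed separately: Medicaid is pooled across plan types.
PLAN_TYPE_STRATA = [
    ("Private PPO", ("private", "PPO")),
    ("Private HMO", ("private", "HMO")),
    ("Medicaid", ("Medicaid", None)),
    ("Medicare PPO", ("Medicare", "PPO")),
    ("Medicare HMO", ("Medicare", "HMO")),
]


class DegenerateInputError(ValueError):
    """Input admits no test statistic (zero variance / all-zero differences)."""


@dataclass
class CorrelationResult:
    x_attribute: str
    y_attribute: str
    stratum: str
    n: int
    r: float
    p_value: float


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with two-sided p (t-transform, n-2 df), listwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    obs = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[obs], y[obs]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def wilcoxon_signed_rank(differences) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped and ties mid-ranked.  The exact null
    distribution is used for n <= 25 when the absolute differences are
    tie-free; otherwise the normal approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all differences are zero")
    absd = np.abs(d)
    tie_free = len(np.unique(absd)) == n
    method = "exact" if (n <= 25 and tie_free) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative="two-sided", method=method,
                           zero_method="wilcox")
    return float(res.pvalue)


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value, one group against another.

    Exact null distribution when the product of group sizes is <= 400 and
    the pooled sample is tie-free; normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def plan_type_table(agg: pd.DataFrame) -> pd.DataFrame:
    """Per-plan-type means with paired and versus-rest significance tests.

    One row per stratum with: mean member patient-review score, mean
    consumer satisfaction score, the paired Wilcoxon signed-rank p between
    the two (paired within plan), and Mann-Whitney p-values of each column
    against the union of the other strata.  A stratum with no plans yields
    a row of absent values and a warning.
    """
    df = agg[agg["in_analysis"]] if "in_analysis" in agg.columns else agg
    masks = {}
    for label, (cat, ptype) in PLAN_TYPE_STRATA:
        m = df["category"] == cat
        if ptype is not None:
            m &= df["plan_type"] == ptype
        masks[label] = m

    rows = []
    for label, m in masks.items():
        sub = df[m]
        rest = df[~m]
        if len(sub) == 0:
            warnings.warn(f"plan type stratum {label!r} has no plans", stacklevel=2)
            rows.append({"plan_type": label, "n_plans": 0,
                         "mean_patient_review": np.nan,
                         "mean_consumer_satisfaction": np.nan,
                         "wilcoxon_paired_p": np.nan,
                         "mw_patient_review_vs_rest_p": np.nan,
                         "mw_consumer_satisfaction_vs_rest_p": np.nan})
            continue
        ratings = sub["mean_rating"]
        sats = sub["consumer_satisfaction_score"]
        pairs = sub[["mean_rating", "consumer_satisfaction_score"]].dropna()
        diffs = (pairs["mean_rating"] - pairs["consumer_satisfaction_score"]).to_numpy()
        try:
            w_p = wilcoxon_signed_rank(diffs) if len(diffs) else np.nan
        except DegenerateInputError:
            w_p = np.nan
        def _vs_rest(col: str) -> float:
            if len(rest) == 0 or sub[col].notna().sum() == 0 or rest[col].notna().sum() == 0:
                return np.nan
            return mann_whitney(sub[col], rest[col])
        rows.append({
            "plan_type": label,
            "n_plans": len(sub),
            "mean_patient_review": float(ratings.mean()),
            "mean_consumer_satisfaction": float(sats.mean()),
            "wilcoxon_paired_p": w_p,
            "mw_patient_review_vs_rest_p": _vs_rest("mean_rating"),
            "mw_consumer_satisfaction_vs_rest_p": _vs_rest("consumer_satisfaction_score"),
        })
    return pd.DataFrame(rows)


def _corr_row(df: pd.DataFrame, x: str, y: str, stratum: str) -> CorrelationResult | None:
    try:
        r, p, n = pearson(df[x], df[y])
    except (ValueError, DegenerateInputError):
        return None
    return CorrelationResult(x, y, stratum, n, r, p)


def statewise_correlations(
    agg: pd.DataFrame,
    x: str = "mean_rating",
    y: str = "consumer_satisfaction_score",
    min_plans: int = 10,
) -> pd.DataFrame:
    """Pooled correlation plus one row per state with at least ``min_plans`` plans."""
    if min_plans < 3:
        raise ValueError("min_plans must be >= 3")
    df = agg[agg["in_analysis"]] if "in_analysis" in agg.columns else agg
    results = []
    overall = _corr_row(df, x, y, "overall")
    if overall is not None:
        results.append(overall)
    for state, sub in df.groupby("state"):
        n_complete = int((~(sub[x].isna() | sub[y].isna())).sum())
        if n_complete < min_plans:
            continue
        row = _corr_row(sub, x, y, str(state))
        if row is not None:
            results.append(row)
    return pd.DataFrame([vars(r) for r in results])


def attribute_correlations(
    agg: pd.DataFrame,
    x_attributes: list[str],
    y: str = "consumer_satisfaction_score",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Pooled correlation of each plan-level aggregate against a plan score."""
    df = agg[agg["in_analysis"]] if "in_analysis" in agg.columns else agg
    rows = [r for x in x_attributes if (r := _corr_row(df, x, y, "overall"))]
    out = pd.DataFrame([vars(r) for r in rows])
    if bh_correction and len(out):
        out["p_bh"] = benjamini_hochberg(out["p_value"])
    return out


def condition_correlations(
    attrs: pd.DataFrame,
    plans: pd.DataFrame,
    membership: dict[str, list],
    cmap: ConditionMap | None = None,
    min_plans: int = 10,
) -> pd.DataFrame:
    """Correlate condition-specialty member ratings with treatment scores.

    For each condition, plan mean ratings are recomputed over the members
    whose specialty the condition maps to, then correlated with the
    condition's treatment-score column.  Conditions with no matching
    providers are skipped with a warning.
    """
    cmap = cmap or ConditionMap()
    cmap.validate(list(plans.columns))
    pairs = [(pid, npi) for pid, ids in membership.items() for npi in ids]
    long = pd.DataFrame(pairs, columns=["plan_id", "npi"]).merge(
        attrs[["npi", "user_rating", "specialty"]], on="npi", how="inner")
    plan_scores = plans.set_index("plan_id")

    results = []
    for cond in cmap.conditions:
        sub = long[long["specialty"].isin(cond.specialties)]
        if len(sub) == 0:
            warnings.warn(f"condition {cond.name!r} has no matching providers",
                          stacklevel=2)
            continue
        per_plan = sub.groupby("plan_id")["user_rating"].mean()
        joined = pd.DataFrame({
            "x": per_plan,
            "y": plan_scores.loc[per_plan.index, cond.score_column],
        }).dropna()
        if len(joined) < max(3, min_plans):
            logger.info("condition %s: only %d plans, skipped", cond.name, len(joined))
            continue
        row = _corr_row(joined, "x", "y", cond.name)
        if row is not None:
            row.x_attribute = "mean_specialty_rating"
            row.y_attribute = cond.score_column
            results.append(row)
    return pd.DataFrame([vars(r) for r in results])
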