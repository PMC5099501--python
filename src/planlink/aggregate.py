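"""Plan-level aggregation of member-provider attributes.

A provider is a member of every plan that one of its accepted-insurer name
strings maps to; a plan's aggregate row holds arithmetic means of its
members' attributes (ratings averaged over rated members only, relative
cost over members with a cost present) joined to the plan's own quality
scores.  Plans with incomplete score data or fewer than ``min_members``
members are excluded from correlation analysis and counted in the log.

Score columns are recognized by the ``_score`` suffix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PlanAggregate:
    """Per-plan aggregate of member-provider attributes."""

    plan_id: str
    state: str
    category: str
    plan_type: str
    n_members: int
    mean_rating: float
    mean_referrals: float
    cc_ratio: float
    mean_hospital_score: float
    mean_hospital_rank: float
    mean_relative_cost: float


def score_columns(plans: pd.DataFrame) -> list[str]:
    return [c for c in plans.columns if c.endswith("_score")]


def plan_membership(
    plans: pd.DataFrame,
    provider_insurers: pd.DataFrame,
    insurance_mapping: dict[str, str],
) -> dict[str, list]:
    """Map each plan to the set of providers whose insurer strings reach it.

    ``provider_insurers`` has one row per provider with a ``;``-joined
    ``insurers`` string column; ``insurance_mapping`` maps raw insurer
    strings to plan names.  Providers with no mapped insurer belong to no
    plan.
    """
    name_to_id = dict(zip(plans["plan_name"], plans["plan_id"]))
    members: dict[str, set] = {pid: set() for pid in plans["plan_id"]}
    for pid_col, ins in zip(provider_insurers["provider_id"],
                            provider_insurers["insurers"]):
        if not isinstance(ins, str) or not ins:
            continue
        for raw in ins.split(";"):
            plan_name = insurance_mapping.get(raw)
            if plan_name is None:
                continue
            plan_id = name_to_id.get(plan_name)
            if plan_id is not None:
                members[plan_id].add(pid_col)
    return {pid: sorted(m) for pid, m in members.items()}


def aggregate_plan(plan: pd.Series, member_attrs: pd.DataFrame) -> PlanAggregate:
    """Aggregate one plan's member attribute rows (member set must be nonempty)."""
    if len(member_attrs) == 0:
        raise ValueError(f"plan {plan['plan_id']} has an empty member set")
    return PlanAggregate(
        plan_id=plan["plan_id"],
        state=plan["state"],
        category=plan["category"],
        plan_type=plan["plan_type"],
        n_members=len(member_attrs),
        mean_rating=float(member_attrs["user_rating"].mean()),
        mean_referrals=float(member_attrs["num_referrals"].mean()),
        cc_ratio=float(member_attrs["castle_connolly"].mean()),
        mean_hospital_score=float(member_attrs["hospital_score"].mean()),
        mean_hospital_rank=float(member_attrs["hospital_rank"].astype(float).mean()),
        mean_relative_cost=float(member_attrs["relative_cost"].mean()),
    )


AGG_COLUMNS = ["mean_rating", "mean_referrals", "cc_ratio",
               "mean_hospital_score", "mean_hospital_rank", "mean_relative_cost"]


def aggregate_plans(
    plans: pd.DataFrame,
    membership: dict[str, list],
    attrs: pd.DataFrame,
    min_members: int = 5,
) -> pd.DataFrame:
    """Build the plan-level analysis table.

    One row per plan with at least one member; ``in_analysis`` marks rows
    with ``n_members >= min_members`` and complete plan scores — the rows
    the correlation battery uses.  Empty and under-sized plans are logged.
    """
    pairs = [(pid, npi) for pid, ids in membership.items() for npi in ids]
    long = pd.DataFrame(pairs, columns=["plan_id", "npi"])
    long = long.merge(attrs, on="npi", how="inner")
    if len(long) == 0:
        empty = plans.iloc[0:0][["plan_id", "plan_name", "state", "category", "plan_type"]]
        return empty.assign(n_members=0, in_analysis=False,
                            **{c: np.nan for c in AGG_COLUMNS})

    g = long.groupby("plan_id")
    agg = pd.DataFrame({
        "n_members": g.size(),
        "mean_rating": g["user_rating"].mean(),
        "mean_referrals": g["num_referrals"].mean(),
        "cc_ratio": g["castle_connolly"].mean(),
        "mean_hospital_score": g["hospital_score"].mean(),
        "mean_hospital_rank": g["hospital_rank"].mean(),
        "mean_relative_cost": g["relative_cost"].mean(),
    }).reset_index()

    out = plans.merge(agg, on="plan_id", how="inner")
    n_empty = len(plans) - len(out)
    if n_empty:
        logger.info("aggregate: %d plans with empty member sets excluded", n_empty)
    scores = score_columns(plans)
    complete = out[scores].notna().all(axis=1) if scores else pd.Series(True, index=out.index)
    big_enough = out["n_members"] >= min_members
    out["in_analysis"] = complete & big_enough
    n_small = int((~big_enough).sum())
    if n_small:
        logger.info("aggregate: %d plans below min_members=%d excluded from analysis",
                    n_small, min_members)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.info("aggregate: %d plans with incomplete scores excluded from analysis",
                    n_incomplete)
    return out.reset_index(drop=True)


def state_summaries(
    plans: pd.DataFrame,
    providers: pd.DataFrame,
    populations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-state mean consumer satisfaction, providers per 1000, plans evaluated.

    ``n_plans_evaluated`` counts plans with complete score data, mirroring
    the exclusion of incomplete plans from the evaluated set.
    """
    if (populations["population"] <= 0).any():
        raise ValueError("populations must be positive")
    pop = populations.set_index("state")["population"]
    missing = set(providers["state"].unique()) - set(pop.index)
    if missing:
        raise ValueError(f"missing population for states with providers: {sorted(missing)}")

    scores = score_columns(plans)
    complete = plans[scores].notna().all(axis=1) if scores else pd.Series(True, index=plans.index)
    sat = plans.groupby("state")["consumer_satisfaction_score"].mean()
    n_eval = plans[complete].groupby("state").size()
    prov_counts = providers.groupby("state").size()

    states = sorted(set(pop.index) & (set(plans["state"]) | set(providers["state"])))
    return pd.DataFrame({
        "state": states,
        "mean_consumer_satisfaction": [float(sat.get(s, np.nan)) for s in states],
        "providers_per_1000": [1000.0 * float(prov_counts.get(s, 0)) / float(pop[s])
                               for s in states],
        "n_plans_evaluated": [int(n_eval.get(s, 0)) for s in states],
    })
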