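"""Model-style front end for the plan-quality correlation analysis.

`PlanQualityAnalysis` is constructed from the plan-level aggregate table
(optionally with the provider attribute table and membership map, which
enable the condition-specialty analysis); `fit()` runs the full battery and
returns a `PlanQualityResults` with the result tables and a text summary.

    model = PlanQualityAnalysis.from_tables(plans, attrs, membership)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import aggregate as agg_mod
from . import stats as stats_mod
from .mappings import ConditionMap

#: Plan-level aggregates correlated against the consumer satisfaction score.
DEFAULT_X_ATTRIBUTES = [
    "mean_rating", "mean_referrals", "cc_ratio",
    "mean_hospital_rank", "mean_relative_cost",
]


@dataclass
class PlanQualityResults:
    """Fitted result tables from the correlation battery."""

    attribute_correlations: pd.DataFrame
    statewise_correlations: pd.DataFrame
    plan_type_stats: pd.DataFrame
    condition_correlations: pd.DataFrame | None = None
    n_plans: int = 0

    def pooled_r(self, x_attribute: str = "mean_rating") -> float:
        tbl = self.attribute_correlations
        row = tbl[tbl["x_attribute"] == x_attribute]
        return float(row["r"].iloc[0]) if len(row) else float("nan")

    def summary(self) -> str:
        lines = [
            "Plan quality correlation analysis",
            "=" * 60,
            f"Plans in analysis: {self.n_plans}",
            "",
            "Attribute correlations vs consumer satisfaction score:",
        ]
        for row in self.attribute_correlations.itertuples():
            lines.append(f"  {row.x_attribute:<22s} r={row.r:+.3f}  "
                         f"p={row.p_value:.3g}  n={row.n}")
        lines += ["", "State-wise correlation (patient rating vs satisfaction):"]
        for row in self.statewise_correlations.itertuples():
            lines.append(f"  {row.stratum:<12s} r={row.r:+.3f}  "
                         f"p={row.p_value:.3g}  n={row.n}")
        lines += ["", "Plan-type statistics:"]
        for row in self.plan_type_stats.itertuples():
            lines.append(
                f"  {row.plan_type:<14s} review={row.mean_patient_review:6.2f}  "
                f"satisfaction={row.mean_consumer_satisfaction:6.2f}  "
                f"paired Wilcoxon p={row.wilcoxon_paired_p:.3g}")
        if self.condition_correlations is not None and len(self.condition_correlations):
            lines += ["", "Condition-specialty correlations:"]
            for row in self.condition_correlations.itertuples():
                lines.append(f"  {row.stratum:<32s} r={row.r:+.3f}  "
                             f"p={row.p_value:.3g}  n={row.n}")
        return "\n".join(lines)


@dataclass
class PlanQualityAnalysis:
    """Correlation analysis of plan quality scores vs member-provider attributes.

    Parameters
    ----------
    plan_aggregates : table from :func:`planlink.aggregate.aggregate_plans`
        (plan scores joined to member-attribute means, with ``in_analysis``).
    attrs, membership : optional provider attribute table and plan->members
        map; required for the condition-specialty analysis.
    """

    plan_aggregates: pd.DataFrame
    attrs: pd.DataFrame | None = None
    membership: dict | None = None
    condition_map: ConditionMap = field(default_factory=ConditionMap)
    x_attributes: list[str] = field(default_factory=lambda: list(DEFAULT_X_ATTRIBUTES))
    y_attribute: str = "consumer_satisfaction_score"
    min_plans_per_state: int = 10

    @classmethod
    def from_tables(
        cls,
        plans: pd.DataFrame,
        attrs: pd.DataFrame,
        membership: dict[str, list],
        min_members: int = 5,
        **kwargs,
    ) -> "PlanQualityAnalysis":
        """Build the model straight from plan, attribute and membership tables."""
        aggregates = agg_mod.aggregate_plans(plans, membership, attrs,
                                             min_members=min_members)
        return cls(plan_aggregates=aggregates, attrs=attrs, membership=membership,
                   **kwargs)

    def fit(self, bh_correction: bool = False) -> PlanQualityResults:
        agg = self.plan_aggregates
        attr_corr = stats_mod.attribute_correlations(
            agg, self.x_attributes, y=self.y_attribute, bh_correction=bh_correction)
        statewise = stats_mod.statewise_correlations(
            agg, x="mean_rating", y=self.y_attribute,
            min_plans=self.min_plans_per_state)
        type_stats = stats_mod.plan_type_table(agg)
        cond = None
        if self.attrs is not None and self.membership is not None:
            plan_cols = ["plan_id"] + agg_mod.score_columns(agg)
            cond = stats_mod.condition_correlations(
                self.attrs, agg[plan_cols], self.membership, cmap=self.condition_map,
                min_plans=self.min_plans_per_state)
        n_plans = int(agg["in_analysis"].sum()) if "in_analysis" in agg.columns else len(agg)
        return PlanQualityResults(
            attribute_correlations=attr_corr,
            statewise_correlations=statewise,
            plan_type_stats=type_stats,
            condition_correlations=cond,
            n_plans=n_plans,
        )
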