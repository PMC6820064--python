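"""Deterministic cohort decision tree.

Expected-value analysis of the two observation strategies.  Each arm accrues
``observation_hours x effective hourly rate`` in cost and carries a
postdischarge biphasic-anaphylaxis probability; the incremental
cost-effectiveness ratio (ICER) is

    ICER = (cost_extended - cost_short) / (p_short - p_extended)

per additional biphasic episode identified under medical observation.  Death
outcomes multiply the postdischarge probability by the case fatality, with
the extended arm further multiplied by the protective relative risk
r = 1/fold, giving a second ICER in dollars per death prevented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .params import (
    HCP,
    SOCIETAL,
    CostInputs,
    FatalityInputs,
    ModelConfig,
    ValidationError,
)

__all__ = [
    "CohortResult",
    "arm_cost",
    "icer_per_biphasic",
    "arm_death_probability",
    "icer_per_death",
    "dominance_category",
    "run_cohort",
    "cohort_table",
    "cost_per_death_table",
]


def arm_cost(hours: float, costs: CostInputs) -> float:
    """Observation cost for one arm: duration times the perspective's rate."""
    if hours < 0:
        raise ValidationError("observation hours must be nonnegative")
    return hours * costs.effective_hourly


def icer_per_biphasic(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost per additional biphasic episode observed.

    Returns NaN when the incremental effect is zero; use
    :func:`dominance_category` to label such comparisons.
    """
    if delta_effect == 0:
        return math.nan
    return delta_cost / delta_effect


def dominance_category(delta_cost: float, delta_effect: float) -> str:
    """Standard CEA labels for the incremental comparison.

    ``delta_effect`` is the gain of the extended arm (episodes observed or
    deaths averted); ``delta_cost`` its extra cost.
    """
    if delta_effect > 0 and delta_cost <= 0:
        return "extended_dominant"
    if delta_effect <= 0 and delta_cost >= 0:
        if delta_effect == 0 and delta_cost == 0:
            return "equivalent"
        return "extended_dominated"
    return "icer"


def arm_death_probability(
    p_postdischarge: float,
    fatality: FatalityInputs,
    relative_risk_applied: bool,
) -> float:
    """Expected deaths per patient in one arm.

    The protective relative risk attaches to the arm as a whole: the extended
    strategy's postdischarge events carry fatality CF*r, the short strategy's
    carry CF.  This is the only algebra consistent with the tree's
    cost-per-death outputs.
    """
    p = p_postdischarge * fatality.case_fatality
    if relative_risk_applied:
        p *= fatality.observed_relative_risk
    return p


def icer_per_death(
    delta_cost: float, deaths_short: float, deaths_extended: float
) -> float:
    """Incremental cost per death prevented; NaN when no deaths are averted."""
    denom = deaths_short - deaths_extended
    if denom <= 0:
        return math.nan
    return delta_cost / denom


@dataclass(frozen=True)
class CohortResult:
    """Expected-value outcomes of the two-arm decision tree."""

    perspective: str
    cost_short: float
    cost_extended: float
    p_postdischarge_short: float
    p_postdischarge_extended: float
    delta_cost: float
    delta_biphasic_observed: float
    icer_per_biphasic: float
    deaths_short: float
    deaths_extended: float
    icer_per_death: float
    dominance_biphasic: str
    dominance_death: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> pd.DataFrame:
        """Two-row arm summary with the incremental column, report rounding
        (cents for costs, one decimal for percentages, whole-dollar ICER)."""
        rows = [
            {
                "strategy": "short",
                "cost_usd": round(self.cost_short, 2),
                "postdischarge_biphasic_pct": round(
                    100 * self.p_postdischarge_short, 1
                ),
                "icer_per_biphasic_usd": round(self.icer_per_biphasic)
                if math.isfinite(self.icer_per_biphasic)
                else math.nan,
            },
            {
                "strategy": "extended",
                "cost_usd": round(self.cost_extended, 2),
                "postdischarge_biphasic_pct": round(
                    100 * self.p_postdischarge_extended, 1
                ),
                "icer_per_biphasic_usd": math.nan,
            },
        ]
        return pd.DataFrame(rows)


def run_cohort(config: ModelConfig) -> CohortResult:
    """Evaluate the decision tree at the base-case (cohort) inputs."""
    short, ext = config.short_strategy, config.extended_strategy
    cost_s = arm_cost(short.observation_hours, config.costs)
    cost_e = arm_cost(ext.observation_hours, config.costs)
    p_s = short.postdischarge_biphasic_prob
    p_e = ext.postdischarge_biphasic_prob
    d_cost = cost_e - cost_s
    d_eff = p_s - p_e
    deaths_s = arm_death_probability(p_s, config.fatality, relative_risk_applied=False)
    deaths_e = arm_death_probability(p_e, config.fatality, relative_risk_applied=True)
    return CohortResult(
        perspective=config.costs.perspective,
        cost_short=cost_s,
        cost_extended=cost_e,
        p_postdischarge_short=p_s,
        p_postdischarge_extended=p_e,
        delta_cost=d_cost,
        delta_biphasic_observed=d_eff,
        icer_per_biphasic=icer_per_biphasic(d_cost, d_eff),
        deaths_short=deaths_s,
        deaths_extended=deaths_e,
        icer_per_death=icer_per_death(d_cost, deaths_s, deaths_e),
        dominance_biphasic=dominance_category(d_cost, d_eff),
        dominance_death=dominance_category(d_cost, deaths_s - deaths_e),
    )


def cohort_table(config: ModelConfig) -> pd.DataFrame:
    """Cohort rows of the main results table for the configured perspective."""
    res = run_cohort(config)
    tbl = res.summary()
    tbl.insert(0, "perspective", res.perspective)
    tbl["strategy"] = [
        config.short_strategy.label,
        config.extended_strategy.label,
    ]
    return tbl


def cost_per_death_table(
    config: ModelConfig,
    folds: tuple[float, ...] = (10.0, 1000.0),
    perspectives: tuple[str, ...] = (HCP, SOCIETAL),
) -> pd.DataFrame:
    """Cost per death prevented, by perspective and fold risk reduction."""
    rows = []
    for persp in perspectives:
        for fold in folds:
            res = run_cohort(config.with_perspective(persp).with_fold(fold))
            rows.append(
                {
                    "perspective": persp,
                    "fold_reduction": fold,
                    "delta_cost_usd": round(res.delta_cost, 2),
                    "deaths_short": res.deaths_short,
                    "deaths_extended": res.deaths_extended,
                    "icer_per_death_usd": round(res.icer_per_death),
                }
            )
    return pd.DataFrame(rows)
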