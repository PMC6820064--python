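"""Deterministic sensitivity analysis.

One-way parameter sweeps of the cohort ICER, closed-form break-even
thresholds (with a bisection cross-check), and tornado-diagram rows.

All quantities here are deterministic functions of the base case; the
closed forms follow directly from the tree algebra:

* risk threshold      p* = p_extended + delta_cost / WTP
* hourly-cost threshold  c* = WTP * delta_p / extra_hours
* relative-risk threshold r* = (p_short*CF - delta_cost/WTP_death) / (p_extended*CF)
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import run_cohort
from .params import SOCIETAL, ModelConfig, ValidationError

__all__ = [
    "ThresholdResult",
    "threshold_biphasic_risk",
    "threshold_hourly_cost",
    "threshold_relative_risk",
    "one_way_sweep",
    "solve_threshold_numeric",
    "tornado",
    "set_parameter",
    "SWEEPABLE_PARAMETERS",
]

SWEEPABLE_PARAMETERS = (
    "direct_hourly",
    "indirect_hourly",
    "extended_hours",
    "p_short",
    "p_extended",
    "case_fatality",
)


@dataclass(frozen=True)
class ThresholdResult:
    """A break-even value: on the ``direction`` side of ``threshold_value``
    the extended strategy meets the willingness-to-pay used."""

    parameter: str
    threshold_value: float
    wtp_used: float
    direction: str  # "above" | "below"

    def rounded(self, ndigits: int = 0, percent: bool = False) -> float:
        x = self.threshold_value * (100.0 if percent else 1.0)
        return round(x, ndigits) if ndigits else float(round(x))


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a config with one deterministic input replaced."""
    if name == "direct_hourly":
        return dataclasses.replace(
            config, costs=dataclasses.replace(config.costs, direct_hourly=value)
        )
    if name == "indirect_hourly":
        return dataclasses.replace(
            config, costs=dataclasses.replace(config.costs, indirect_hourly=value)
        )
    if name == "extended_hours":
        return dataclasses.replace(
            config,
            extended_strategy=dataclasses.replace(
                config.extended_strategy, observation_hours=value
            ),
        )
    if name == "p_short":
        return dataclasses.replace(
            config,
            short_strategy=dataclasses.replace(
                config.short_strategy, postdischarge_biphasic_prob=value
            ),
        )
    if name == "p_extended":
        return dataclasses.replace(
            config,
            extended_strategy=dataclasses.replace(
                config.extended_strategy, postdischarge_biphasic_prob=value
            ),
        )
    if name == "case_fatality":
        return dataclasses.replace(
            config,
            fatality=dataclasses.replace(config.fatality, case_fatality=value),
        )
    raise ValidationError(f"unknown parameter {name!r}")


def threshold_biphasic_risk(config: ModelConfig, wtp: float | None = None) -> ThresholdResult:
    """Short-arm postdischarge risk above which extending is cost-effective."""
    if wtp is None:
        wtp = config.wtp_per_biphasic
    if wtp <= 0:
        raise ValidationError("willingness-to-pay must be positive")
    base = run_cohort(config)
    p_star = base.p_postdischarge_extended + base.delta_cost / wtp
    return ThresholdResult("p_short", p_star, wtp, "above")


def threshold_hourly_cost(
    config: ModelConfig, wtp: float | None = None, include_indirect: bool = False
) -> ThresholdResult:
    """Hourly observation cost below which extending is cost-effective.

    By default the threshold is on the direct-cost scale (indirect costs
    excluded); with ``include_indirect`` it is on the combined societal rate.
    """
    if wtp is None:
        wtp = config.wtp_per_biphasic
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be nonnegative")
    extra_hours = (
        config.extended_strategy.observation_hours
        - config.short_strategy.observation_hours
    )
    if extra_hours <= 0:
        raise ValidationError("extended stay must exceed the short stay")
    delta_p = (
        config.short_strategy.postdischarge_biphasic_prob
        - config.extended_strategy.postdischarge_biphasic_prob
    )
    c_star = wtp * delta_p / extra_hours
    name = "effective_hourly" if include_indirect else "direct_hourly"
    return ThresholdResult(name, c_star, wtp, "below")


def threshold_relative_risk(
    config: ModelConfig, wtp_death: float | None = None
) -> ThresholdResult:
    """Largest protective relative risk r (extended vs short arm death per
    biphasic event) at which extending meets the per-death willingness-to-pay.

    r* <= 0 means no attainable threshold; the value is capped at 1 (no
    protection needed) when observation is free.
    """
    if wtp_death is None:
        wtp_death = config.wtp_per_death
    if wtp_death <= 0:
        raise ValidationError("willingness-to-pay must be positive")
    base = run_cohort(config)
    cf = config.fatality.case_fatality
    num = base.p_postdischarge_short * cf - base.delta_cost / wtp_death
    den = base.p_postdischarge_extended * cf
    r_star = num / den
    if r_star <= 0:
        raise ValidationError(
            "extended observation cannot reach the per-death threshold for any "
            "relative risk at these inputs"
        )
    return ThresholdResult("observed_relative_risk", min(r_star, 1.0), wtp_death, "below")


def one_way_sweep(
    config: ModelConfig, parameter: str, lo: float, hi: float, n_points: int
) -> pd.DataFrame:
    """ICER per biphasic observed over a grid of one input, others at base."""
    if not lo < hi:
        raise ValidationError("sweep requires lo < hi")
    if n_points < 2:
        raise ValidationError("sweep needs at least 2 grid points")
    grid = np.linspace(lo, hi, n_points)
    icers = [
        run_cohort(set_parameter(config, parameter, float(v))).icer_per_biphasic
        for v in grid
    ]
    return pd.DataFrame({parameter: grid, "icer_per_biphasic": icers})


def solve_threshold_numeric(
    objective: Callable[[float], float],
    target: float,
    bracket: tuple[float, float],
    tol: float = 1e-12,
) -> float:
    """Root of ``objective(x) == target`` on a bracketing interval.

    Independent numeric route (Brent bisection) used to cross-check the
    closed-form thresholds.
    """
    lo, hi = bracket
    f = lambda x: objective(x) - target
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValidationError(
            f"target {target} not bracketed on [{lo}, {hi}] "
            f"(objective endpoints {flo + target:.6g}, {fhi + target:.6g})"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def default_tornado_ranges(config: ModelConfig) -> dict[str, tuple[float, float]]:
    """Simulation (min, max) ranges of every sampled input."""
    ranges = {
        name: (dist.min, dist.max) for name, dist in config.distributions.items()
    }
    if config.costs.perspective != SOCIETAL:
        ranges.pop("indirect_hourly", None)
    return ranges


def tornado(
    config: ModelConfig,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One row per input: ICER at each extreme, sorted by descending span."""
    if ranges is None:
        ranges = default_tornado_ranges(config)
    rows = []
    for name, (lo, hi) in ranges.items():
        icer_lo = run_cohort(set_parameter(config, name, lo)).icer_per_biphasic
        icer_hi = run_cohort(set_parameter(config, name, hi)).icer_per_biphasic
        rows.append(
            {
                "parameter": name,
                "low_input": lo,
                "high_input": hi,
                "icer_at_low": icer_lo,
                "icer_at_high": icer_hi,
                "span": abs(icer_hi - icer_lo),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["span", "parameter"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
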