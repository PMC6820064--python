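"""Probabilistic sensitivity analysis (Monte Carlo simulation).

Each iteration draws every uncertain input from its triangular distribution
(inverse-CDF transform of a single seeded uniform stream, one fixed column
order per iteration), prices both arms, and records the draws.  Summaries
report per-arm means/SDs; the headline ICER is the ratio of mean incremental
cost to mean incremental effect — not the mean of per-iteration ratios,
which is ill-behaved when the effect difference can approach zero.

The same pipeline runs with moment-matched beta (probabilities, fatality)
and gamma (costs) alternates as a distributional robustness check, with the
extended stay fixed at 6 or 24 hours per scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    PARAM_NAMES,
    SOCIETAL,
    ModelConfig,
    ValidationError,
    mean_matched_alternate,
)

__all__ = [
    "PsaSummary",
    "PsaResult",
    "run_psa",
    "icer_of_means",
    "psa_death_icer",
    "ceac",
    "alternate_distribution_psa",
]

#: Iteration-table column order (documented interface; do not reorder).
ITERATION_COLUMNS = [
    "iteration",
    "direct_hourly",
    "indirect_hourly",
    "extended_hours",
    "p_short",
    "p_extended",
    "case_fatality",
    "cost_short",
    "cost_extended",
]


@dataclass(frozen=True)
class PsaSummary:
    """Monte Carlo means/SDs and ratio-of-means ICERs for one perspective."""

    perspective: str
    n_iterations: int
    mean_cost_short: float
    sd_cost_short: float
    mean_cost_extended: float
    sd_cost_extended: float
    mean_p_short: float
    sd_p_short: float
    mean_p_extended: float
    sd_p_extended: float
    icer_per_biphasic: float
    icer_per_death: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["icer_per_death"] = {str(k): v for k, v in self.icer_per_death.items()}
        return d


class PsaResult:
    """Iteration table plus summary accessors for one probabilistic run."""

    def __init__(self, config: ModelConfig, iterations: pd.DataFrame, seed: int):
        self.config = config
        self.iterations = iterations
        self.seed = seed

    @property
    def delta_cost(self) -> pd.Series:
        return self.iterations["cost_extended"] - self.iterations["cost_short"]

    @property
    def delta_effect(self) -> pd.Series:
        return self.iterations["p_short"] - self.iterations["p_extended"]

    def death_icer(self, fold: float) -> float:
        return psa_death_icer(self.iterations, fold)

    def summary(self, folds: tuple[float, ...] = (10.0, 1000.0)) -> PsaSummary:
        it = self.iterations
        n = len(it)
        ddof = 1 if n > 1 else 0
        sd = lambda col: float(it[col].std(ddof=ddof)) if n > 1 else 0.0
        mean_d_eff = float(self.delta_effect.mean())
        icer = (
            float(self.delta_cost.mean()) / mean_d_eff
            if mean_d_eff != 0
            else math.nan
        )
        return PsaSummary(
            perspective=self.config.costs.perspective,
            n_iterations=n,
            mean_cost_short=float(it["cost_short"].mean()),
            sd_cost_short=sd("cost_short"),
            mean_cost_extended=float(it["cost_extended"].mean()),
            sd_cost_extended=sd("cost_extended"),
            mean_p_short=float(it["p_short"].mean()),
            sd_p_short=sd("p_short"),
            mean_p_extended=float(it["p_extended"].mean()),
            sd_p_extended=sd("p_extended"),
            icer_per_biphasic=icer,
            icer_per_death={fold: self.death_icer(fold) for fold in folds},
        )

    def ceac(self, wtp_grid) -> pd.DataFrame:
        return ceac(self.iterations, wtp_grid)


def _price_arms(it: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    """Attach per-arm costs given sampled rates and durations."""
    rate = it["direct_hourly"].to_numpy().copy()
    if config.costs.perspective == SOCIETAL:
        rate = rate + it["indirect_hourly"].to_numpy()
    short_hours = config.short_strategy.observation_hours
    it["cost_short"] = short_hours * rate
    it["cost_extended"] = it["extended_hours"].to_numpy() * rate
    return it[ITERATION_COLUMNS]


def run_psa(
    config: ModelConfig, n_iter: int | None = None, seed: int | None = None
) -> PsaResult:
    """Sample all triangular inputs for ``n_iter`` iterations.

    The indirect-cost column is drawn under both perspectives (it is simply
    not priced under the healthcare-sector one), so a given seed yields the
    identical uniform stream, and identical sampled columns, either way.
    """
    n = config.n_iterations if n_iter is None else int(n_iter)
    if n < 1:
        raise ValidationError("need at least one iteration")
    seed = config.seed if seed is None else seed
    missing = [p for p in PARAM_NAMES if p not in config.distributions]
    if missing:
        raise ValidationError(f"missing distributions for {missing}")
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(PARAM_NAMES)))
    it = pd.DataFrame({"iteration": np.arange(n)})
    for j, name in enumerate(PARAM_NAMES):
        it[name] = config.distributions[name].ppf(u[:, j])
    return PsaResult(config, _price_arms(it, config), seed)


def icer_of_means(summary: PsaSummary) -> float:
    """Ratio-of-means ICER recomputed from a summary's first moments."""
    d_eff = summary.mean_p_short - summary.mean_p_extended
    if d_eff == 0:
        return math.nan
    return (summary.mean_cost_extended - summary.mean_cost_short) / d_eff


def psa_death_icer(iterations: pd.DataFrame, fold: float) -> float:
    """Mean incremental cost over mean incremental deaths at a fixed fold
    fatality-risk reduction (the fold is a scenario, not a sampled input)."""
    if fold < 1:
        raise ValidationError("fold reduction must be >= 1")
    cf = iterations["case_fatality"]
    deaths_short = iterations["p_short"] * cf
    deaths_ext = iterations["p_extended"] * cf / fold
    mean_d_deaths = float((deaths_short - deaths_ext).mean())
    if mean_d_deaths == 0:
        return math.nan
    d_cost = iterations["cost_extended"] - iterations["cost_short"]
    return float(d_cost.mean()) / mean_d_deaths


def ceac(iterations: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the extended strategy.

    Acceptability at a willingness-to-pay w is the fraction of iterations
    with positive incremental net monetary benefit
    w*(p_short - p_extended) - (cost_extended - cost_short).
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValidationError("willingness-to-pay grid must be nonempty")
    d_eff = (iterations["p_short"] - iterations["p_extended"]).to_numpy()
    d_cost = (iterations["cost_extended"] - iterations["cost_short"]).to_numpy()
    nmb = wtp_grid[:, None] * d_eff[None, :] - d_cost[None, :]
    return pd.DataFrame(
        {"wtp": wtp_grid, "acceptability": (nmb > 0).mean(axis=1)}
    )


def alternate_distribution_psa(
    config: ModelConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    extended_hours: float = 6.0,
) -> PsaResult:
    """Robustness run with beta/gamma alternates in place of triangulars.

    Each alternate is moment-matched: mean at the cohort base-case value,
    variance equal to the corresponding triangular's.  The extended stay is
    held fixed (6- or 24-hour scenario) rather than sampled.
    """
    n = config.n_iterations if n_iter is None else int(n_iter)
    if n < 1:
        raise ValidationError("need at least one iteration")
    seed = config.seed if seed is None else seed
    dists = config.distributions
    specs = {
        "direct_hourly": mean_matched_alternate(
            config.costs.direct_hourly, "gamma", dists["direct_hourly"].var()
        ),
        "indirect_hourly": mean_matched_alternate(
            config.costs.indirect_hourly, "gamma", dists["indirect_hourly"].var()
        ),
        "p_short": mean_matched_alternate(
            config.short_strategy.postdischarge_biphasic_prob,
            "beta",
            dists["p_short"].var(),
        ),
        "p_extended": mean_matched_alternate(
            config.extended_strategy.postdischarge_biphasic_prob,
            "beta",
            dists["p_extended"].var(),
        ),
        "case_fatality": mean_matched_alternate(
            config.fatality.case_fatality, "beta", dists["case_fatality"].var()
        ),
    }
    rng = np.random.default_rng(seed)
    it = pd.DataFrame({"iteration": np.arange(n)})
    for name in PARAM_NAMES:  # fixed draw order, as in run_psa
        if name == "extended_hours":
            it[name] = np.full(n, float(extended_hours))
        else:
            it[name] = specs[name].sample(rng, n)
    scenario = config.with_extended_hours(extended_hours)
    return PsaResult(scenario, _price_arms(it, scenario), seed)
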