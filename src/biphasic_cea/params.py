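"""Model inputs for the postanaphylaxis-observation cost-effectiveness model.

The decision problem compares a short (1 hour) symptom-free observation after
resolved anaphylaxis against an extended stay (6-24 hours).  Every quantity
the model consumes lives here:

* hourly observation costs (direct, and indirect job-opportunity costs that
  are counted only under the societal perspective), in 2019 US dollars;
* postdischarge biphasic-anaphylaxis probabilities for each strategy
  (5.0% after 1 hour, 2.7% after >=6 hours, i.e. one minus the pooled
  negative predictive values 95% and 97.3%);
* case fatality of a postdischarge biphasic event (0.33%) and the relative
  risk of death when the event instead occurs under medical observation
  (a 10- to 1000-fold reduction, expressed as r = 1/fold);
* the triangular min/mode/max distributions used by the probabilistic
  sensitivity analysis, and moment-matched beta/gamma alternates used to
  validate it.

A single :class:`ModelConfig` bundles everything, can be loaded from a
JSON/YAML file, and is immutable; derived scenarios (societal perspective,
1000-fold risk reduction, 4-hour stay) are produced by the ``with_*``
helpers rather than mutation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "TriangularDist",
    "AlternateDistSpec",
    "CostInputs",
    "StrategyParams",
    "FatalityInputs",
    "ModelConfig",
    "HCP",
    "SOCIETAL",
    "PERSPECTIVES",
    "PARAM_NAMES",
    "npv_to_risk",
    "sample_triangular",
    "triangular_moments",
    "mean_matched_alternate",
    "default_distributions",
    "default_config",
    "load_config",
    "save_config",
]

HCP = "healthcare_sector"
SOCIETAL = "societal"
PERSPECTIVES = (HCP, SOCIETAL)

#: Fixed per-iteration sampling order for the probabilistic analysis.
PARAM_NAMES = (
    "direct_hourly",
    "indirect_hourly",
    "extended_hours",
    "p_short",
    "p_extended",
    "case_fatality",
)


class ValidationError(ValueError):
    """A model input violates its admissibility constraints."""


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangularDist:
    """Triangular distribution given by minimum, mode and maximum.

    Edge-degenerate shapes (mode == min or mode == max) are routine here:
    several inputs use the base-case value as both mode and upper bound,
    e.g. Tri(6, 6, 24) hours or Tri(1, 5, 5)%.  The fully degenerate point
    mass min == mode == max is also accepted so that a probabilistic run can
    be collapsed onto the deterministic cohort analysis exactly.
    """

    min: float
    mode: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mode <= self.max):
            raise ValidationError(
                f"triangular requires min <= mode <= max, got "
                f"({self.min}, {self.mode}, {self.max})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.min == self.max

    def ppf(self, u):
        """Inverse CDF (two-branch square-root form); u=0 -> min, u=1 -> max."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValidationError("uniform deviate must lie in [0, 1]")
        a, m, b = self.min, self.mode, self.max
        if self.is_degenerate:
            return np.full_like(u, a) if u.ndim else float(a)
        fc = (m - a) / (b - a)
        lower = a + np.sqrt(u * (b - a) * (m - a))
        upper = b - np.sqrt((1.0 - u) * (b - a) * (b - m))
        x = np.where(u <= fc, lower, upper)
        return float(x) if x.ndim == 0 else x

    def mean(self) -> float:
        return (self.min + self.mode + self.max) / 3.0

    def var(self) -> float:
        a, m, b = self.min, self.mode, self.max
        return (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0

    def sd(self) -> float:
        return math.sqrt(self.var())


def sample_triangular(dist: TriangularDist, u):
    """Map uniform deviate(s) ``u`` through the triangular inverse CDF."""
    return dist.ppf(u)


def triangular_moments(dist: TriangularDist) -> tuple[float, float]:
    """Closed-form (mean, sd) of a triangular distribution."""
    return dist.mean(), dist.sd()


@dataclass(frozen=True)
class AlternateDistSpec:
    """Beta (probabilities) or gamma (costs) alternate, specified by moments.

    ``variance == 0`` denotes the point-mass limit at ``mean``.
    """

    family: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.mean <= 0:
            raise ValidationError("mean must be positive")
        if self.variance < 0:
            raise ValidationError("variance must be nonnegative")
        if self.family == "beta":
            if not 0 < self.mean < 1:
                raise ValidationError("beta mean must lie in (0, 1)")
            if self.variance >= self.mean * (1.0 - self.mean):
                raise ValidationError(
                    "beta variance must be below mean*(1-mean) "
                    f"({self.mean * (1 - self.mean):.6g}), got {self.variance:.6g}"
                )

    def shape_params(self) -> tuple[float, float]:
        """(alpha, beta) for beta; (shape, scale) for gamma."""
        if self.variance == 0:
            raise ValidationError("point mass has no shape parameters")
        if self.family == "beta":
            nu = self.mean * (1.0 - self.mean) / self.variance - 1.0
            return self.mean * nu, (1.0 - self.mean) * nu
        shape = self.mean**2 / self.variance
        return shape, self.variance / self.mean

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.variance == 0:
            return np.full(size, self.mean)
        a, b = self.shape_params()
        if self.family == "beta":
            return rng.beta(a, b, size)
        return rng.gamma(a, b, size)


def mean_matched_alternate(
    cohort_value: float, family: str, variance: float
) -> AlternateDistSpec:
    """Alternate distribution with mean pinned at the cohort (base-case) value."""
    return AlternateDistSpec(family=family, mean=cohort_value, variance=variance)


def npv_to_risk(npv: float) -> float:
    """Postdischarge event risk implied by a negative predictive value."""
    if not 0.0 <= npv <= 1.0:
        raise ValidationError(f"NPV must lie in [0, 1], got {npv}")
    return 1.0 - npv


# ---------------------------------------------------------------------------
# Structured inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostInputs:
    direct_hourly: float = 286.92
    indirect_hourly: float = 27.77
    perspective: str = HCP

    def __post_init__(self) -> None:
        if self.direct_hourly <= 0:
            raise ValidationError("direct hourly cost must be positive")
        if self.indirect_hourly < 0:
            raise ValidationError("indirect hourly cost must be nonnegative")
        if self.perspective not in PERSPECTIVES:
            raise ValidationError(
                f"perspective must be one of {PERSPECTIVES}, got {self.perspective!r}"
            )

    @property
    def effective_hourly(self) -> float:
        """Hourly rate charged to the chosen perspective."""
        if self.perspective == SOCIETAL:
            return self.direct_hourly + self.indirect_hourly
        return self.direct_hourly


@dataclass(frozen=True)
class StrategyParams:
    label: str
    observation_hours: float
    postdischarge_biphasic_prob: float

    def __post_init__(self) -> None:
        if self.observation_hours < 1:
            raise ValidationError("observation must last at least 1 hour")
        if not 0.0 < self.postdischarge_biphasic_prob < 1.0:
            raise ValidationError("postdischarge probability must lie in (0, 1)")


@dataclass(frozen=True)
class FatalityInputs:
    """Case fatality of a postdischarge biphasic event and the protective
    relative risk r = 1/fold attributed to being under observation."""

    case_fatality: float = 0.0033
    observed_relative_risk: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fatality < 1.0:
            raise ValidationError("case fatality must lie in (0, 1)")
        if not 0.0 < self.observed_relative_risk <= 1.0:
            raise ValidationError("relative risk must lie in (0, 1]")

    @property
    def fold(self) -> float:
        return 1.0 / self.observed_relative_risk

    @classmethod
    def from_fold(cls, fold: float, case_fatality: float = 0.0033) -> "FatalityInputs":
        if fold < 1:
            raise ValidationError("fold reduction must be >= 1")
        return cls(case_fatality=case_fatality, observed_relative_risk=1.0 / fold)


def default_distributions() -> dict[str, TriangularDist]:
    """Base-case triangular distributions for every sampled parameter."""
    return {
        "direct_hourly": TriangularDist(100.0, 286.92, 500.0),
        "indirect_hourly": TriangularDist(0.0, 27.77, 50.0),
        "extended_hours": TriangularDist(6.0, 6.0, 24.0),
        "p_short": TriangularDist(0.01, 0.05, 0.05),
        "p_extended": TriangularDist(0.01, 0.027, 0.027),
        "case_fatality": TriangularDist(0.0025, 0.0033, 0.0033),
    }


@dataclass(frozen=True)
class ModelConfig:
    short_strategy: StrategyParams = field(
        default_factory=lambda: StrategyParams("1-h observation", 1.0, 0.05)
    )
    extended_strategy: StrategyParams = field(
        default_factory=lambda: StrategyParams("6-h observation", 6.0, 0.027)
    )
    costs: CostInputs = field(default_factory=CostInputs)
    fatality: FatalityInputs = field(default_factory=FatalityInputs)
    distributions: Mapping[str, TriangularDist] = field(
        default_factory=default_distributions
    )
    wtp_per_biphasic: float = 10_000.0
    wtp_per_death: float = 10_000_000.0
    horizon_hours: float = 78.0
    n_iterations: int = 10_000
    seed: int = 2019

    def __post_init__(self) -> None:
        for name in self.distributions:
            if name not in PARAM_NAMES:
                raise ValidationError(f"unknown sampled parameter {name!r}")
        ext = self.distributions.get("extended_hours")
        if ext is not None and self.horizon_hours < ext.max:
            raise ValidationError("horizon must cover the longest extended stay")
        if self.extended_strategy.observation_hours <= self.short_strategy.observation_hours:
            raise ValidationError("extended stay must exceed the short stay")
        if self.wtp_per_biphasic <= 0 or self.wtp_per_death <= 0:
            raise ValidationError("willingness-to-pay thresholds must be positive")
        if self.n_iterations < 1:
            raise ValidationError("need at least one simulation iteration")

    # -- scenario helpers ---------------------------------------------------

    def with_perspective(self, perspective: str) -> "ModelConfig":
        return dataclasses.replace(
            self, costs=dataclasses.replace(self.costs, perspective=perspective)
        )

    def with_fold(self, fold: float) -> "ModelConfig":
        return dataclasses.replace(
            self,
            fatality=FatalityInputs.from_fold(fold, self.fatality.case_fatality),
        )

    def with_extended_hours(self, hours: float) -> "ModelConfig":
        """Alternative stay length; the postdischarge risk is kept at the
        extended arm's base value (the model has no risk data between 1 and
        5 hours, so e.g. the 4-hour scenario reuses 2.7%)."""
        return dataclasses.replace(
            self,
            extended_strategy=dataclasses.replace(
                self.extended_strategy,
                label=f"{hours:g}-h observation",
                observation_hours=hours,
            ),
        )

    def as_point_masses(self) -> "ModelConfig":
        """Collapse every sampled distribution onto the base-case value."""
        points = {
            "direct_hourly": self.costs.direct_hourly,
            "indirect_hourly": self.costs.indirect_hourly,
            "extended_hours": self.extended_strategy.observation_hours,
            "p_short": self.short_strategy.postdischarge_biphasic_prob,
            "p_extended": self.extended_strategy.postdischarge_biphasic_prob,
            "case_fatality": self.fatality.case_fatality,
        }
        return dataclasses.replace(
            self,
            distributions={k: TriangularDist(v, v, v) for k, v in points.items()},
        )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "short_strategy": dataclasses.asdict(self.short_strategy),
            "extended_strategy": dataclasses.asdict(self.extended_strategy),
            "costs": dataclasses.asdict(self.costs),
            "fatality": dataclasses.asdict(self.fatality),
            "distributions": {
                k: [d.min, d.mode, d.max] for k, d in self.distributions.items()
            },
            "wtp_per_biphasic": self.wtp_per_biphasic,
            "wtp_per_death": self.wtp_per_death,
            "horizon_hours": self.horizon_hours,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        kwargs: dict = {}
        for key in ("short_strategy", "extended_strategy"):
            if key in data:
                kwargs[key] = _strategy_from_dict(data[key])
        if "costs" in data:
            kwargs["costs"] = CostInputs(**data["costs"])
        if "fatality" in data:
            fat = dict(data["fatality"])
            if "fold" in fat:
                kwargs["fatality"] = FatalityInputs.from_fold(
                    fat["fold"], fat.get("case_fatality", 0.0033)
                )
            else:
                kwargs["fatality"] = FatalityInputs(**fat)
        if "distributions" in data:
            kwargs["distributions"] = {
                k: TriangularDist(*v) for k, v in data["distributions"].items()
            }
        for key in (
            "wtp_per_biphasic",
            "wtp_per_death",
            "horizon_hours",
            "n_iterations",
            "seed",
        ):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


def _strategy_from_dict(data: Mapping) -> StrategyParams:
    data = dict(data)
    # Both conventions are accepted: the risk itself, or the NPV it derives from.
    if "npv" in data and "postdischarge_biphasic_prob" not in data:
        data["postdischarge_biphasic_prob"] = npv_to_risk(data.pop("npv"))
    else:
        data.pop("npv", None)
    return StrategyParams(**data)


def default_config(perspective: str = HCP, fold: float = 10.0) -> ModelConfig:
    """The shipped base case (healthcare-sector perspective, 10-fold reduction)."""
    return ModelConfig().with_perspective(perspective).with_fold(fold)


def load_config(path: str | Path) -> ModelConfig:
    """Read a JSON or YAML config file mirroring :meth:`ModelConfig.to_dict`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return ModelConfig.from_dict(data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def packaged_default_config() -> ModelConfig:
    """Load the YAML file shipped with the package (identical to defaults)."""
    with resources.as_file(
        resources.files("biphasic_cea.data") / "default_config.yaml"
    ) as p:
        return load_config(p)
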