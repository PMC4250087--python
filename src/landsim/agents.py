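"""Agent functional types: production from capitals, thresholds, benefit.

An *agent functional type* (AFT) groups land managers by their productive
response to land endowments, in analogy to plant functional types. Each AFT
converts per-cell capitals into ecosystem-service output through a
Cobb-Douglas utilisation factor

    u(cell) = prod_c capital_c(cell) ** sensitivity_c,

which multiplies the type's optimal per-service production, so that a type
produces exactly its optimal (tabulated) output where every capital it is
sensitive to equals 1.

Behaviour is reduced to two thresholds per agent: the *abandonment
threshold* (minimum utility below which the occupant vacates its cell) and
the *competition threshold* (utility margin a challenger must exceed to
displace it). Thresholds are constant per type or drawn per agent from a
Gaussian clamped at zero.

The *benefit* (utility) function maps the unmet-demand fraction of a service
to the value of producing one unit of it: linear ``max(a*x, 0)`` with zero
floor, or exponential ``exp(x)`` which stays positive under oversupply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .world import CROP, NATURAL

__all__ = [
    "FOOD",
    "RECREATION",
    "SERVICES",
    "AFT_PRESETS",
    "AFTSpec",
    "Agent",
    "BenefitFunction",
    "ThresholdSpec",
    "benefit_value",
    "capital_utilisation",
    "get_preset",
    "production_vector",
    "sample_thresholds",
]

FOOD = "food"
RECREATION = "recreation"
#: Service ordering used throughout arrays: index 0 = food, 1 = recreation.
SERVICES = (FOOD, RECREATION)


@dataclass(frozen=True)
class ThresholdSpec:
    """Specification of a per-agent threshold in utility units.

    ``constant`` always yields ``mean``; ``gaussian`` draws from
    Normal(mean, sd) clamped below at 0 (a negative willingness threshold is
    meaningless).
    """

    kind: str = "constant"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gaussian"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return self.mean
        return max(0.0, float(rng.normal(self.mean, self.sd)))


def sample_thresholds(spec: ThresholdSpec, rng: np.random.Generator) -> float:
    """Draw one threshold value from ``spec`` (constant specs ignore ``rng``)."""
    return spec.sample(rng)


@dataclass(frozen=True)
class AFTSpec:
    """An agent functional type.

    ``sensitivities`` are the Cobb-Douglas exponents over capitals;
    ``optimal_production`` is the per-service output (units per cell per
    timestep) attained where all capitals equal 1.
    """

    name: str
    sensitivities: Mapping[str, float]
    optimal_production: Mapping[str, float]
    abandonment: ThresholdSpec = ThresholdSpec()
    competition: ThresholdSpec = ThresholdSpec()

    def __post_init__(self) -> None:
        for c, s in self.sensitivities.items():
            if s < 0:
                raise ValueError(f"{self.name}: sensitivity to {c} must be >= 0")
        for svc, p in self.optimal_production.items():
            if p < 0:
                raise ValueError(f"{self.name}: optimal production of {svc} must be >= 0")

    def with_thresholds(
        self,
        abandonment: ThresholdSpec | None = None,
        competition: ThresholdSpec | None = None,
    ) -> "AFTSpec":
        """Copy of this type with replaced threshold specifications."""
        return replace(
            self,
            abandonment=abandonment or self.abandonment,
            competition=competition or self.competition,
        )


@dataclass(frozen=True)
class Agent:
    """A land-manager instance: its type plus thresholds sampled at creation.

    Thresholds are fixed for the agent's lifetime.
    """

    aft: AFTSpec
    abandonment_threshold: float
    competition_threshold: float

    @classmethod
    def spawn(cls, aft: AFTSpec, rng: np.random.Generator) -> "Agent":
        return cls(
            aft=aft,
            abandonment_threshold=aft.abandonment.sample(rng),
            competition_threshold=aft.competition.sample(rng),
        )


def capital_utilisation(aft: AFTSpec, capitals: Mapping[str, float]) -> float:
    """Cobb-Douglas utilisation factor in [0, 1] at the given capital levels.

    ``0**0`` is defined as 1 (a capital the type is insensitive to never
    limits it); missing capitals are treated as irrelevant only if the
    sensitivity to them is zero.
    """
    factor = 1.0
    for name, sens in aft.sensitivities.items():
        value = capitals[name]
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"capital {name!r}={value} outside [0, 1]")
        if sens == 0.0:
            continue  # 0**0 == 1 by convention
        factor *= value**sens
    return factor


def production_vector(aft: AFTSpec, capitals: Mapping[str, float]) -> dict[str, float]:
    """Per-service production of ``aft`` on a cell with the given capitals."""
    u = capital_utilisation(aft, capitals)
    return {svc: p * u for svc, p in aft.optimal_production.items()}


@dataclass(frozen=True)
class BenefitFunction:
    """Maps the unmet-demand fraction x to benefit per unit of service.

    linear:      max(gradient * x, 0)  — oversupply is neither rewarded nor
                 punished (zero floor)
    exponential: exp(x) — strictly positive even under oversupply, modelling
                 insensitivity to demand levels or tradable surpluses
    """

    form: str = "linear"
    gradient: float = 3.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "exponential"):
            raise ValueError(f"unknown benefit form {self.form!r}")

    def __call__(self, x):
        """Benefit at unmet fraction ``x`` (scalar or ndarray)."""
        if self.form == "linear":
            return np.maximum(self.gradient * np.asarray(x, dtype=float), 0.0)[()]
        return np.exp(np.asarray(x, dtype=float))[()]


def benefit_value(fn: BenefitFunction, x: float) -> float:
    """Benefit per unit of service at unmet-demand fraction ``x``."""
    return float(fn(x))


def _preset(name, crop_sens, nat_sens, food, rec) -> AFTSpec:
    return AFTSpec(
        name=name,
        sensitivities={CROP: crop_sens, NATURAL: nat_sens},
        optimal_production={FOOD: food, RECREATION: rec},
    )


#: The six agent functional types used by the experiment catalogue, with
#: zero thresholds (experiments override thresholds per Table-row).
AFT_PRESETS: dict[str, AFTSpec] = {
    spec.name: spec
    for spec in (
        _preset("high_intensity_farmer", 1.0, 0.0, 1.0, 0.0),
        _preset("mid_intensity_farmer_1", 0.5, 0.0, 0.5, 0.0),
        _preset("low_intensity_farmer_1", 0.25, 0.0, 0.25, 0.0),
        _preset("mid_intensity_farmer_2", 0.75, 0.20, 0.75, 0.15),
        _preset("low_intensity_farmer_2", 0.35, 0.4, 0.35, 0.4),
        _preset("conservationist", 0.0, 1.0, 0.0, 1.0),
    )
}


def get_preset(name: str) -> AFTSpec:
    try:
        return AFT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown AFT preset {name!r}; known: {sorted(AFT_PRESETS)}"
        ) from None
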