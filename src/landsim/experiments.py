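"""The experiment catalogue: 19 parameterisations x 4 demand/scope variants.

Each experiment is identified by a code like ``"3b"``: the number selects a
row of the parameter table (thresholds per type, search effort, benefit
form, roster) and the letter the demand/scope variant:

    a = static globalised     b = dynamic globalised
    c = static regionalised   d = dynamic regionalised

Rosters: experiments 1-8 field the high-intensity farmer and the
conservationist; 9-13 add the single-function mid- and low-intensity
farmers; 14-19 use their multifunctional counterparts (which also produce
recreation). Experiment 7 reduces search effort to 100 iterations;
experiments 8, 12, 13 and 19 use the exponential benefit form.

Demand is calibrated per roster so that an optimal configuration is almost
capable of satisfying the (equal, static) global demands; dynamic variants
drop recreation demand by 75% after timestep 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

from .agents import AFT_PRESETS, BenefitFunction, ThresholdSpec, get_preset
from .engine import EngineConfig
from .market import build_demand_schedule, calibrate_demand
from .world import GradientSpec, generate_capital_grids, make_region_map

__all__ = [
    "ExperimentConfig",
    "VARIANTS",
    "build_config",
    "config_diff",
    "experiment_catalogue",
]

VARIANTS = {
    "a": ("static", 1),
    "b": ("dynamic", 1),
    "c": ("static", 2),
    "d": ("dynamic", 2),
}

_CONST0 = ThresholdSpec("constant", 0.0)
_GAUSS = ThresholdSpec("gaussian", 0.2, 0.03)


def _c(v: float) -> ThresholdSpec:
    return ThresholdSpec("constant", v)


# Per-experiment settings: thresholds are (abandonment, competition) per
# role; absent roles take zero thresholds. Roles map onto presets via the
# roster for the experiment's block.
_ROW: dict[int, dict[str, Any]] = {
    1: {},
    2: {"hif": (_c(0.2), None)},
    3: {"cons": (_c(0.2), None)},
    4: {"hif": (_c(0.2), None), "cons": (_c(0.2), None)},
    5: {"cons": (_GAUSS, None)},
    6: {"cons": (None, _GAUSS)},
    7: {"search_iterations": 100},
    8: {"benefit": "exponential"},
    9: {},
    10: {"hif": (_c(0.2), None), "cons": (_c(0.2), None)},
    11: {"mif": (None, _c(0.1)), "lif": (None, _c(0.2))},
    12: {"benefit": "exponential"},
    13: {"mif": (None, _c(0.1)), "lif": (None, _c(0.2)), "benefit": "exponential"},
    14: {},
    15: {"hif": (_c(0.2), None), "cons": (_c(0.2), None)},
    16: {"hif": (_GAUSS, None), "cons": (_GAUSS, None)},
    17: {"mif": (_GAUSS, None), "lif": (_GAUSS, None)},
    18: {"mif": (None, _c(0.1)), "lif": (None, _c(0.2))},
    19: {"benefit": "exponential"},
}

_ROLE_KEYS = ("hif", "mif", "lif", "cons")


def _roster_names(experiment: int) -> tuple[str, ...]:
    if experiment <= 8:
        return ("high_intensity_farmer", "conservationist")
    suffix = "1" if experiment <= 13 else "2"
    return (
        "high_intensity_farmer",
        f"mid_intensity_farmer_{suffix}",
        f"low_intensity_farmer_{suffix}",
        "conservationist",
    )


def _role_of(name: str) -> str:
    if name.startswith("high"):
        return "hif"
    if name.startswith("mid"):
        return "mif"
    if name.startswith("low"):
        return "lif"
    return "cons"


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully resolved experiment parameterisation.

    Holds the catalogue-level settings; :meth:`to_engine_config` constructs
    the arena, calibrates demand for the roster and assembles the
    :class:`~landsim.engine.EngineConfig` actually run.
    """

    code: str
    experiment: int
    variant: str
    width: int = 60
    height: int = 60
    timesteps: int = 25
    n_reps: int = 30
    base_seed: int = 0
    headroom: float = 0.02
    search_iterations: int = 5000
    cells_per_search: int = 10
    benefit_form: str = "linear"
    benefit_gradient: float = 3.0
    thresholds: Mapping[str, tuple[ThresholdSpec, ThresholdSpec]] = field(
        default_factory=dict
    )
    gradient: GradientSpec = GradientSpec()
    change_timestep: int = 11
    drop_fraction: float = 0.75

    @property
    def demand_variant(self) -> str:
        return VARIANTS[self.variant][0]

    @property
    def per_side(self) -> int:
        return VARIANTS[self.variant][1]

    @property
    def multifunctional(self) -> bool:
        return self.experiment >= 14

    def roster(self):
        """The experiment's AFT specs with its thresholds applied."""
        out = []
        for name in _roster_names(self.experiment):
            spec = get_preset(name)
            ab, ct = self.thresholds.get(_role_of(name), (_CONST0, _CONST0))
            out.append(spec.with_thresholds(abandonment=ab, competition=ct))
        return tuple(out)

    def to_engine_config(self) -> EngineConfig:
        world = generate_capital_grids(self.width, self.height, self.gradient)
        regions = make_region_map(self.width, self.height, self.per_side)
        afts = self.roster()
        base = calibrate_demand(world, afts, headroom=self.headroom)
        demand = build_demand_schedule(
            base,
            variant=self.demand_variant,
            n_regions=regions.n_regions,
            timesteps=self.timesteps,
            change_timestep=self.change_timestep,
            drop_fraction=self.drop_fraction,
        )
        return EngineConfig(
            world=world,
            regions=regions,
            afts=afts,
            demand=demand,
            benefit=BenefitFunction(self.benefit_form, self.benefit_gradient),
            search_iterations=self.search_iterations,
            cells_per_search=self.cells_per_search,
            timesteps=self.timesteps,
        )


def _parse_code(code: str) -> tuple[int, str]:
    code = code.strip().lower()
    if len(code) < 2 or code[-1] not in VARIANTS:
        raise ValueError(f"malformed experiment code {code!r}")
    try:
        experiment = int(code[:-1])
    except ValueError:
        raise ValueError(f"malformed experiment code {code!r}") from None
    if experiment not in _ROW:
        raise ValueError(f"unknown experiment {experiment} (known: 1-19)")
    return experiment, code[-1]


def _make_config(experiment: int, variant: str) -> ExperimentConfig:
    row = _ROW[experiment]
    thresholds = {}
    for role in _ROLE_KEYS:
        if role in row:
            ab, ct = row[role]
            thresholds[role] = (ab or _CONST0, ct or _CONST0)
    return ExperimentConfig(
        code=f"{experiment}{variant}",
        experiment=experiment,
        variant=variant,
        search_iterations=row.get("search_iterations", 5000),
        benefit_form=row.get("benefit", "linear"),
        thresholds=thresholds,
    )


def experiment_catalogue() -> dict[str, ExperimentConfig]:
    """All 76 experiment configurations at the full default scale."""
    return {
        f"{e}{v}": _make_config(e, v) for e in sorted(_ROW) for v in "abcd"
    }


def build_config(code: str, **overrides: Any) -> ExperimentConfig:
    """Catalogue entry for ``code`` with scale/seed overrides applied.

    Accepted overrides: ``width``, ``height``, ``timesteps``, ``n_reps``,
    ``base_seed``, ``headroom``, ``search_iterations``, ``cells_per_search``.
    Regionalised variants always use quadrant regions, so width and height
    must stay divisible by 2.
    """
    experiment, variant = _parse_code(code)
    cfg = _make_config(experiment, variant)
    allowed = {
        "width",
        "height",
        "timesteps",
        "n_reps",
        "base_seed",
        "headroom",
        "search_iterations",
        "cells_per_search",
    }
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown overrides: {sorted(unknown)}")
    cfg = replace(cfg, **overrides)
    if cfg.width % cfg.per_side or cfg.height % cfg.per_side:
        raise ValueError(
            f"grid {cfg.width}x{cfg.height} not divisible into "
            f"{cfg.per_side}x{cfg.per_side} regions"
        )
    if cfg.cells_per_search > cfg.width * cfg.height:
        raise ValueError("cells_per_search exceeds the number of cells")
    return cfg


_DIFF_FIELDS = (
    "search_iterations",
    "cells_per_search",
    "benefit_form",
)


def config_diff(cfg: ExperimentConfig, base: ExperimentConfig) -> dict[str, tuple]:
    """Fields on which ``cfg`` deviates from ``base`` (same variant).

    Compares the catalogue-level knobs the parameter table varies: roster,
    per-role thresholds, search effort and benefit form. Used to verify that
    each experiment differs from the baseline in exactly its advertised
    settings.
    """
    out: dict[str, tuple] = {}
    for f in _DIFF_FIELDS:
        a, b = getattr(cfg, f), getattr(base, f)
        if a != b:
            out[f] = (a, b)
    if _roster_names(cfg.experiment) != _roster_names(base.experiment):
        out["roster"] = (
            _roster_names(cfg.experiment),
            _roster_names(base.experiment),
        )
    for role in _ROLE_KEYS:
        a = cfg.thresholds.get(role, (_CONST0, _CONST0))
        b = base.thresholds.get(role, (_CONST0, _CONST0))
        if a[0] != b[0]:
            out[f"{role}.abandonment"] = (a[0], b[0])
        if a[1] != b[1]:
            out[f"{role}.competition"] = (a[1], b[1])
    return out
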