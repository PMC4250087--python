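"""Demand schedules, supply accounting and competitiveness.

Demand for each ecosystem service is exogenous. It is expressed either for
the whole arena (globalised) or split equally across regions (regionalised);
the step change used in the dynamic experiments drops recreation demand by a
fixed fraction after a given timestep while food demand is unchanged.

Unmet demand is normalised to a dimensionless fraction of demand at the
relevant scope, ``x = (demand - supply) / demand`` (0 when demand is 0), so
that benefit gradients, thresholds of order 0.1-0.2 and the exponential
benefit form all operate on a common O(1) scale. ``x`` is negative under
oversupply.

An agent's *competitiveness* at a cell is the sum over services of the
benefit of that service's unmet fraction (at the cell's scope) times the
agent's production of the service on that cell. It drives both takeover and
abandonment in the engine.

The module also provides the brute-force *optimal allocation* oracle —
each cell assigned to the type maximising total production there — used to
calibrate demand so that an optimum configuration is almost, but not quite,
capable of satisfying the global demands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .agents import FOOD, RECREATION, SERVICES, AFTSpec, BenefitFunction
from .world import CapitalGrid, RegionMap

__all__ = [
    "DemandSchedule",
    "MarketState",
    "build_demand_schedule",
    "calibrate_demand",
    "competitiveness",
    "compute_supply",
    "optimal_allocation",
    "production_arrays",
    "unmet_fraction",
]


def production_arrays(world: CapitalGrid, afts: Sequence[AFTSpec]) -> np.ndarray:
    """Per-cell production of every AFT, vectorised over the whole arena.

    Returns an array of shape ``(n_afts, n_cells, n_services)`` with the
    service ordering of :data:`landsim.agents.SERVICES`. Capitals are static,
    so this is computed once per (world, roster) pair.
    """
    n_cells = world.n_cells
    out = np.empty((len(afts), n_cells, len(SERVICES)))
    for a, spec in enumerate(afts):
        util = np.ones(n_cells)
        for cap_name, sens in spec.sensitivities.items():
            if sens == 0.0:
                continue
            util *= world.flat(cap_name) ** sens
        for s, svc in enumerate(SERVICES):
            out[a, :, s] = spec.optimal_production.get(svc, 0.0) * util
    return out


@dataclass(frozen=True)
class DemandSchedule:
    """Per-timestep demand levels for each service.

    ``levels`` has shape ``(timesteps + 1, n_services)`` and holds the
    *global* demand at each timestep (index 0 is the pre-step initial
    market); regional demand is the global level divided equally among
    ``n_regions``. A dynamic schedule multiplies recreation demand by
    ``1 - drop_fraction`` at every timestep after ``change_timestep``.
    """

    levels: np.ndarray
    n_regions: int
    change_timestep: int | None = None
    drop_fraction: float = 0.0

    @property
    def timesteps(self) -> int:
        return self.levels.shape[0] - 1

    def global_demand(self, t: int) -> np.ndarray:
        """Global demand per service at timestep ``t`` (shape (n_services,))."""
        return self.levels[t]

    def regional(self, t: int) -> np.ndarray:
        """Demand per region per service at ``t`` (shape (n_regions, n_services))."""
        return np.tile(self.levels[t] / self.n_regions, (self.n_regions, 1))


def build_demand_schedule(
    base: float,
    variant: str = "static",
    n_regions: int = 1,
    timesteps: int = 25,
    change_timestep: int = 11,
    drop_fraction: float = 0.75,
) -> DemandSchedule:
    """Build a static or dynamic (step-change) demand schedule.

    Both services start at the same base demand. Under the ``dynamic``
    variant, recreation demand at every timestep strictly after
    ``change_timestep`` equals ``(1 - drop_fraction) * base``; food demand is
    unchanged throughout.
    """
    if variant not in ("static", "dynamic"):
        raise ValueError(f"unknown demand variant {variant!r}")
    if not (0.0 <= drop_fraction <= 1.0):
        raise ValueError(f"drop_fraction must be in [0, 1], got {drop_fraction}")
    if variant == "dynamic" and not (0 <= change_timestep < timesteps):
        raise ValueError(
            f"change_timestep={change_timestep} must lie within the horizon {timesteps}"
        )
    levels = np.full((timesteps + 1, len(SERVICES)), float(base))
    if variant == "dynamic":
        rec = SERVICES.index(RECREATION)
        levels[change_timestep + 1 :, rec] = base * (1.0 - drop_fraction)
    return DemandSchedule(
        levels=levels,
        n_regions=n_regions,
        change_timestep=change_timestep if variant == "dynamic" else None,
        drop_fraction=drop_fraction if variant == "dynamic" else 0.0,
    )


def optimal_allocation(
    world: CapitalGrid, afts: Sequence[AFTSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Assign every cell to the AFT with the largest total production there.

    Ties are broken by declaration order (first listed type wins). Returns
    ``(assignment, supplies)``: a flat per-cell AFT-index array and the
    per-service total supplies of the assignment.
    """
    if not afts:
        raise ValueError("need at least one AFT")
    prod = production_arrays(world, afts)  # (A, C, S)
    totals = prod.sum(axis=2)  # (A, C)
    assignment = np.argmax(totals, axis=0)  # first max wins ties
    supplies = prod[assignment, np.arange(world.n_cells), :].sum(axis=0)
    return assignment, supplies


def calibrate_demand(
    world: CapitalGrid, afts: Sequence[AFTSpec], headroom: float = 0.02
) -> float:
    """Base demand level such that demands are almost but not quite satisfiable.

    ``D = (1 + headroom) * mean(per-service supplies of the optimal
    allocation)``, used for both services (demands are equal). Because the
    optimal allocation maximises total production cell-by-cell, the summed
    demand ``2 D`` exceeds the total supply of *any* allocation by the
    headroom factor, so no configuration can satisfy both demands at once.
    """
    if headroom <= 0:
        raise ValueError(f"headroom must be > 0, got {headroom}")
    if world.n_cells == 0:
        raise ValueError("empty world")
    _, supplies = optimal_allocation(world, afts)
    return float((1.0 + headroom) * supplies.mean())


def compute_supply(
    allocation: np.ndarray,
    world: CapitalGrid,
    regions: RegionMap,
    afts: Sequence[AFTSpec],
) -> np.ndarray:
    """Per-region, per-service supply of an allocation (-1 = unmanaged).

    Supply of a scope is the summed production of the occupants of its
    cells; global supply is the sum over regions.
    """
    prod = production_arrays(world, afts)
    supply = np.zeros((regions.n_regions, len(SERVICES)))
    occupied = np.flatnonzero(allocation >= 0)
    if occupied.size:
        cell_prod = prod[allocation[occupied], occupied, :]
        np.add.at(supply, regions.flat[occupied], cell_prod)
    return supply


def unmet_fraction(demand, supply):
    """Unmet demand as a fraction of demand: (d - s)/d, 0 where d == 0.

    Works element-wise on arrays; may be negative under oversupply.
    """
    d = np.asarray(demand, dtype=float)
    s = np.asarray(supply, dtype=float)
    if np.any(d < 0):
        raise ValueError("demand must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(d > 0, (d - s) / np.where(d > 0, d, 1.0), 0.0)
    return x[()]


@dataclass
class MarketState:
    """Supply and unmet-demand fractions per region per service.

    Arrays have shape ``(n_regions, n_services)``; the globalised arena is
    the single-region case.
    """

    supply: np.ndarray
    demand: np.ndarray

    @property
    def unmet(self) -> np.ndarray:
        return np.asarray(unmet_fraction(self.demand, self.supply))

    def global_supply(self) -> np.ndarray:
        return self.supply.sum(axis=0)


def competitiveness(
    aft: AFTSpec,
    cell_capitals: Mapping[str, float],
    unmet: Mapping[str, float],
    benefit_fns: Mapping[str, BenefitFunction],
) -> float:
    """Utility an agent of ``aft`` derives from occupying the given cell.

    Sum over services of the per-unit benefit at the cell scope's unmet
    fraction times the type's production on the cell. This is the reference
    (scalar) implementation; the engine evaluates the same quantity from
    precomputed arrays.
    """
    from .agents import production_vector

    prod = production_vector(aft, cell_capitals)
    return float(
        sum(benefit_fns[svc](unmet[svc]) * p for svc, p in prod.items() if p != 0.0)
    )
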