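"""The timestep scheduler: abandonment, stochastic search, takeover, runs.

Each timestep (nominally one year) proceeds as:

1. refresh the market from the current allocation and the timestep's demand
   levels;
2. abandonment pass — occupied cells are visited in randomised order and
   every occupant whose competitiveness does not exceed its abandonment
   threshold vacates, with the market updated incrementally after each
   vacancy (reduced supply raises unmet demand for occupants visited later);
3. search and competition — the active types take turns (round-robin in a
   per-timestep randomised order) running search iterations: each iteration
   samples a fixed number of distinct cells uniformly, ranks them by the
   searching type's prospective competitiveness, and attempts takeovers in
   rank order until one succeeds or the list is exhausted. A takeover
   succeeds iff the cell is unmanaged or the challenger's competitiveness
   exceeds the occupant's by more than the occupant's competition threshold,
   and the challenger's competitiveness exceeds its own freshly sampled
   abandonment threshold. A successful takeover installs a fresh agent with
   newly sampled thresholds and updates the market immediately — new land
   use is implemented at once, which is what makes expansion self-limiting
   as supply approaches demand;
4. record supplies, an allocation snapshot and the timestep's events.

Displaced and abandoning agents are discarded (types, not individuals, are
tracked). All randomness flows from a single per-realisation generator
seeded as ``base_seed + realisation_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agents import SERVICES, AFTSpec, BenefitFunction
from .market import DemandSchedule, MarketState, production_arrays, unmet_fraction
from .world import CapitalGrid, RegionMap

__all__ = [
    "EngineConfig",
    "EventLog",
    "RunResult",
    "SimState",
    "UNMANAGED",
    "abandonment_pass",
    "initialise_state",
    "run_ensemble",
    "run_realisation",
    "search_and_compete",
    "step",
]

#: Allocation value marking an unmanaged cell.
UNMANAGED = -1


@dataclass(frozen=True)
class EngineConfig:
    """Everything needed to run one realisation."""

    world: CapitalGrid
    regions: RegionMap
    afts: tuple[AFTSpec, ...]
    demand: DemandSchedule
    benefit: BenefitFunction = BenefitFunction("linear", 3.0)
    search_iterations: int = 5000
    cells_per_search: int = 10
    timesteps: int = 25

    def __post_init__(self) -> None:
        if not self.afts:
            raise ValueError("need at least one AFT")
        if self.cells_per_search < 1 or self.cells_per_search > self.world.n_cells:
            raise ValueError("cells_per_search must be in [1, n_cells]")
        if self.search_iterations < 0 or self.timesteps < 0:
            raise ValueError("search_iterations and timesteps must be >= 0")
        if self.demand.n_regions != self.regions.n_regions:
            raise ValueError("demand schedule and region map disagree on region count")
        if self.demand.timesteps < self.timesteps:
            raise ValueError("demand schedule shorter than the run horizon")


class EventLog:
    """Flat record of every allocation change.

    Each event is ``(timestep, kind, cell, aft_index, other)`` where for an
    abandonment ``other`` is the occupant's competitiveness at the moment of
    the check, and for a takeover it is the index of the displaced type (or
    UNMANAGED). Margins of successful takeovers are kept alongside so that
    threshold contracts can be audited after a run.
    """

    def __init__(self) -> None:
        self.timestep: list[int] = []
        self.kind: list[str] = []
        self.cell: list[int] = []
        self.aft: list[int] = []
        self.other: list[float] = []
        self.margin: list[float] = []  # takeovers only, NaN for abandonments

    def add_abandonment(self, t: int, cell: int, aft: int, comp: float) -> None:
        self._add(t, "abandonment", cell, aft, comp, float("nan"))

    def add_takeover(self, t: int, cell: int, aft: int, prev: int, margin: float) -> None:
        self._add(t, "takeover", cell, aft, float(prev), margin)

    def _add(self, t, kind, cell, aft, other, margin) -> None:
        self.timestep.append(t)
        self.kind.append(kind)
        self.cell.append(cell)
        self.aft.append(aft)
        self.other.append(other)
        self.margin.append(margin)

    def __len__(self) -> int:
        return len(self.timestep)

    def counts(self, kind: str, timesteps: int) -> np.ndarray:
        """Per-timestep event counts for ``kind`` over ``0..timesteps``."""
        out = np.zeros(timesteps + 1, dtype=int)
        for t, k in zip(self.timestep, self.kind):
            if k == kind:
                out[t] += 1
        return out


@dataclass
class SimState:
    """Mutable state of one realisation.

    ``allocation`` is a flat per-cell AFT index (UNMANAGED = vacant);
    occupant thresholds live in parallel arrays since displaced agents are
    never tracked individually.
    """

    config: EngineConfig
    rng: np.random.Generator
    allocation: np.ndarray
    ab_threshold: np.ndarray
    comp_threshold: np.ndarray
    market: MarketState
    timestep: int = 0
    events: EventLog = field(default_factory=EventLog)
    # --- precomputed, immutable over the run ---
    prod: np.ndarray = None  # (n_afts, n_cells, n_services)
    region_of: np.ndarray = None  # (n_cells,)
    benefit_rs: np.ndarray = None  # (n_regions, n_services), cached benefit values

    def refresh_market(self, demand_rs: np.ndarray) -> None:
        """Recompute supply from the allocation and reset cached benefits."""
        supply = np.zeros_like(demand_rs)
        occ = np.flatnonzero(self.allocation >= 0)
        if occ.size:
            np.add.at(supply, self.region_of[occ], self.prod[self.allocation[occ], occ, :])
        self.market = MarketState(supply=supply, demand=demand_rs)
        self._refresh_benefit()

    def _refresh_benefit(self, region: int | None = None) -> None:
        if region is None:
            self.benefit_rs = np.asarray(
                self.config.benefit(self.market.unmet), dtype=float
            )
        else:
            d = self.market.demand[region]
            s = self.market.supply[region]
            self.benefit_rs[region] = self.config.benefit(unmet_fraction(d, s))

    def comp_at(self, aft: int, cell: int) -> float:
        """Competitiveness of type ``aft`` at ``cell`` under the cached market."""
        b = self.benefit_rs[self.region_of[cell]]
        p = self.prod[aft, cell]
        return float(b[0] * p[0] + b[1] * p[1])

    def _vacate(self, cell: int) -> None:
        aft = self.allocation[cell]
        r = self.region_of[cell]
        self.market.supply[r] -= self.prod[aft, cell]
        self.allocation[cell] = UNMANAGED
        self._refresh_benefit(r)

    def _occupy(self, cell: int, aft: int, ab: float, ct: float) -> None:
        r = self.region_of[cell]
        self.market.supply[r] += self.prod[aft, cell]
        self.allocation[cell] = aft
        self.ab_threshold[cell] = ab
        self.comp_threshold[cell] = ct
        self._refresh_benefit(r)


def initialise_state(config: EngineConfig, seed: int) -> SimState:
    """Random initial state: every cell occupied by a uniformly drawn type.

    Thresholds are sampled per agent at creation; the market is computed for
    the schedule's initial demand levels.
    """
    rng = np.random.default_rng(seed)
    n_cells = config.world.n_cells
    n_afts = len(config.afts)
    allocation = rng.integers(0, n_afts, size=n_cells)
    ab = np.empty(n_cells)
    ct = np.empty(n_cells)
    for cell in range(n_cells):
        spec = config.afts[allocation[cell]]
        ab[cell] = spec.abandonment.sample(rng)
        ct[cell] = spec.competition.sample(rng)
    state = SimState(
        config=config,
        rng=rng,
        allocation=allocation,
        ab_threshold=ab,
        comp_threshold=ct,
        market=None,
        prod=production_arrays(config.world, config.afts),
        region_of=config.regions.flat.astype(np.intp),
    )
    state.refresh_market(config.demand.regional(0))
    return state


def abandonment_pass(state: SimState) -> SimState:
    """Vacate every occupant whose utility does not exceed its threshold.

    Occupied cells are visited in randomised order; the market is updated
    incrementally after each vacancy, so the falling supply raises unmet
    demand (and hence competitiveness) for occupants checked later.
    """
    occupied = np.flatnonzero(state.allocation >= 0)
    if occupied.size == 0:
        return state
    order = state.rng.permutation(occupied)
    t = state.timestep
    for cell in order:
        aft = state.allocation[cell]
        comp = state.comp_at(aft, cell)
        if comp <= state.ab_threshold[cell]:
            state._vacate(cell)
            state.events.add_abandonment(t, int(cell), int(aft), comp)
    return state


def _sample_cells(rng: np.random.Generator, n_cells: int, k: int) -> np.ndarray:
    # fast path: draw with replacement, fall back on collision
    cells = rng.integers(0, n_cells, size=k)
    if len(np.unique(cells)) == k:
        return cells
    return rng.choice(n_cells, size=k, replace=False)


def search_and_compete(state: SimState) -> SimState:
    """Run the timestep's search iterations for every active type.

    Types take turns in a per-timestep randomised round-robin order; each
    iteration samples distinct cells, ranks them by the searching type's
    competitiveness (ranking ties broken by a uniform random draw) and
    attempts takeovers in rank order until one succeeds.
    """
    cfg = state.config
    rng = state.rng
    n_afts = len(cfg.afts)
    n_cells = cfg.world.n_cells
    k = cfg.cells_per_search
    prod = state.prod
    region_of = state.region_of
    alloc = state.allocation
    t = state.timestep
    aft_order = rng.permutation(n_afts)
    ab_specs = [spec.abandonment for spec in cfg.afts]
    ct_specs = [spec.competition for spec in cfg.afts]

    for _ in range(cfg.search_iterations):
        for a in aft_order:
            cells = _sample_cells(rng, n_cells, k)
            b = state.benefit_rs[region_of[cells]]  # (k, S)
            p = prod[a, cells]  # (k, S)
            comp = b[:, 0] * p[:, 0] + b[:, 1] * p[:, 1]
            # descending competitiveness; ties resolved by random keys
            order = np.lexsort((rng.random(k), -comp))
            for idx in order:
                cell = int(cells[idx])
                occupant = alloc[cell]
                if occupant == a:
                    continue  # zero margin can never beat a non-negative threshold
                # failed attempts leave the market untouched, so the ranked
                # competitiveness is still current within this iteration
                c = float(comp[idx])
                ab = ab_specs[a].sample(rng)
                if not c > ab:
                    continue
                if occupant != UNMANAGED:
                    margin = c - state.comp_at(occupant, cell)
                    if not margin > state.comp_threshold[cell]:
                        continue
                    state._vacate(cell)
                else:
                    margin = float("nan")
                state._occupy(cell, int(a), ab, ct_specs[a].sample(rng))
                state.events.add_takeover(t, cell, int(a), int(occupant), margin)
                break
    return state


@dataclass
class RunResult:
    """Time series and snapshots of one realisation.

    ``supply`` and ``demand`` have shape ``(timesteps + 1, n_regions,
    n_services)``; row 0 is the initial state before any dynamics.
    ``snapshots[t]`` is the flat allocation after timestep ``t``.
    """

    seed: int
    aft_names: tuple[str, ...]
    supply: np.ndarray
    demand: np.ndarray
    snapshots: np.ndarray
    events: EventLog
    config: EngineConfig

    @property
    def timesteps(self) -> int:
        return self.supply.shape[0] - 1

    def global_supply(self, service: str | None = None) -> np.ndarray:
        """Global supply series; one service's column if named."""
        g = self.supply.sum(axis=1)
        if service is None:
            return g
        return g[:, SERVICES.index(service)]

    def global_demand(self, service: str | None = None) -> np.ndarray:
        g = self.demand.sum(axis=1)
        if service is None:
            return g
        return g[:, SERVICES.index(service)]

    def final_snapshot(self) -> np.ndarray:
        return self.snapshots[-1]


def step(state: SimState) -> SimState:
    """Advance one timestep: market refresh, abandonment, search, record."""
    if state.timestep >= state.config.timesteps:
        raise ValueError("run horizon already reached")
    state.timestep += 1
    state.refresh_market(state.config.demand.regional(state.timestep))
    abandonment_pass(state)
    search_and_compete(state)
    return state


def run_realisation(config: EngineConfig, seed: int) -> RunResult:
    """Execute the full horizon from a random initial allocation."""
    state = initialise_state(config, seed)
    T = config.timesteps
    n_regions = config.regions.n_regions
    supply = np.empty((T + 1, n_regions, len(SERVICES)))
    demand = np.empty_like(supply)
    snapshots = np.empty((T + 1, config.world.n_cells), dtype=np.int16)
    supply[0] = state.market.supply
    demand[0] = state.market.demand
    snapshots[0] = state.allocation
    for t in range(1, T + 1):
        step(state)
        supply[t] = state.market.supply
        demand[t] = state.market.demand
        snapshots[t] = state.allocation
    return RunResult(
        seed=seed,
        aft_names=tuple(a.name for a in config.afts),
        supply=supply,
        demand=demand,
        snapshots=snapshots,
        events=state.events,
        config=config,
    )


def run_ensemble(
    config: EngineConfig, n_reps: int = 30, base_seed: int = 0
) -> list[RunResult]:
    """Independent realisations with seeds ``base_seed + i``, i = 0..n_reps-1."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [run_realisation(config, base_seed + i) for i in range(n_reps)]
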