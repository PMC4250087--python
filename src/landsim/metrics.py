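"""Ensemble diagnostics and run analyses.

Covers steady-state detection across realisations, land-use composition,
occupancy in capital space, abandonment profiles, a same-type adjacency
index of land-use concentration, and supply per unit of managed land.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import SERVICES
from .engine import UNMANAGED, EventLog, RunResult
from .world import CROP, NATURAL, CapitalGrid

__all__ = [
    "EnsembleSummary",
    "abandonment_profile",
    "adjacency_concentration",
    "capital_space_histogram",
    "detect_steady_state",
    "landuse_composition",
    "occupancy_weighted_capital",
    "productive_efficiency",
    "stabilisation_time",
    "summarise_ensemble",
]


def detect_steady_state(
    supplies: np.ndarray,
    window: Sequence[int] | None = None,
    persistence: int = 3,
) -> int | None:
    """Earliest timestep from which the ensemble is in a steady state.

    The ensemble is steady at timestep ``t`` when, for every service, the
    between-realisation standard deviation of supply exceeds the one-step
    change in the ensemble-mean supply, ``|mean(t) - mean(t-1)|``. The
    detector returns the earliest ``t`` in ``window`` at which this holds
    for ``persistence`` consecutive timesteps (a guard against single-step
    flukes), or None. Degenerate ensembles with zero dispersion never
    qualify (zero is not greater than zero drift).

    ``supplies`` has shape ``(n_realisations, n_timesteps, n_services)`` (a
    trailing service axis of size 1 may be omitted).
    """
    supplies = np.asarray(supplies, dtype=float)
    if supplies.ndim == 2:
        supplies = supplies[:, :, None]
    n_real, n_steps, _ = supplies.shape
    if n_real < 2:
        raise ValueError("steady-state detection needs at least 2 realisations")
    mean = supplies.mean(axis=0)  # (T, S)
    sd = supplies.std(axis=0, ddof=1)  # (T, S)
    drift = np.abs(np.diff(mean, axis=0))  # (T-1, S), drift[t-1] = |m(t)-m(t-1)|
    steady = np.all(sd[1:] > drift, axis=1)  # indexed by t-1, for t = 1..T-1
    if window is None:
        window = range(1, n_steps)
    for t in window:
        if t < 1 or t + persistence - 1 > n_steps - 1:
            continue
        if steady[t - 1 : t - 1 + persistence].all():
            return int(t)
    return None


def landuse_composition(
    snapshot: np.ndarray, aft_names: Sequence[str]
) -> dict[str, float]:
    """Cell share of each type plus the unmanaged share (sums to 1)."""
    snapshot = np.asarray(snapshot).ravel()
    n = snapshot.size
    counts = np.bincount(snapshot[snapshot >= 0], minlength=len(aft_names))
    out = {name: counts[i] / n for i, name in enumerate(aft_names)}
    out["unmanaged"] = np.count_nonzero(snapshot == UNMANAGED) / n
    return out


def capital_space_histogram(
    snapshot: np.ndarray,
    world: CapitalGrid,
    aft_index: int,
    bins: int = 10,
) -> np.ndarray:
    """2-D occupancy counts of one type over (crop, natural) capital bins.

    Bin edges span [0, 1] on both axes; the histogram total equals the
    type's cell count in the snapshot.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    mask = np.asarray(snapshot).ravel() == aft_index
    crop = world.flat(CROP)[mask]
    nat = world.flat(NATURAL)[mask]
    hist, _, _ = np.histogram2d(crop, nat, bins=bins, range=[[0, 1], [0, 1]])
    return hist


def occupancy_weighted_capital(
    snapshot: np.ndarray, world: CapitalGrid, aft_index: int, capital: str = NATURAL
) -> float:
    """Mean capital level over the cells a type occupies (NaN if absent)."""
    mask = np.asarray(snapshot).ravel() == aft_index
    if not mask.any():
        return float("nan")
    return float(world.flat(capital)[mask].mean())


def abandonment_profile(events: EventLog, world: CapitalGrid) -> pd.DataFrame:
    """Per-timestep count and mean capitals of cells vacated by abandonment.

    Empty log -> empty frame. Columns: timestep, count, mean_<capital>...
    """
    rows = [
        (t, c)
        for t, k, c in zip(events.timestep, events.kind, events.cell)
        if k == "abandonment"
    ]
    cap_cols = {f"mean_{name}": world.flat(name) for name in world.names}
    if not rows:
        return pd.DataFrame(columns=["timestep", "count", *cap_cols]).set_index(
            "timestep"
        )
    df = pd.DataFrame(rows, columns=["timestep", "cell"])
    for col, flat in cap_cols.items():
        df[col] = flat[df["cell"]]
    out = df.groupby("timestep").agg(
        count=("cell", "size"), **{c: (c, "mean") for c in cap_cols}
    )
    return out


def adjacency_concentration(snapshot_grid: np.ndarray) -> float:
    """Mean same-type neighbour fraction over managed cells (4-neighbourhood).

    For each managed cell, the fraction of its managed von-Neumann
    neighbours sharing its type; unmanaged cells are excluded from both
    numerator and denominator, and boundary cells use only their existing
    neighbours. Returns NaN when no managed cell has a managed neighbour.
    """
    g = np.asarray(snapshot_grid)
    if g.ndim != 2:
        raise ValueError("snapshot must be a 2-D grid of type indices")
    same = np.zeros(g.shape, dtype=float)
    total = np.zeros(g.shape, dtype=float)
    managed = g != UNMANAGED
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(g, shift, axis=axis)
        nb_managed = np.roll(managed, shift, axis=axis)
        valid = np.ones(g.shape, dtype=bool)  # mask out wrap-around pairs
        if axis == 0:
            valid[0 if shift == 1 else -1, :] = False
        else:
            valid[:, 0 if shift == 1 else -1] = False
        pair = managed & nb_managed & valid
        total += pair
        same += pair & (g == nb)
    with np.errstate(invalid="ignore"):
        frac = same[managed & (total > 0)] / total[managed & (total > 0)]
    return float(frac.mean()) if frac.size else float("nan")


def productive_efficiency(result: RunResult) -> np.ndarray:
    """Global supply per managed cell, per service, per timestep.

    Shape ``(timesteps + 1, n_services)``; 0/0 is defined as 0.
    """
    supply = result.global_supply()  # (T+1, S)
    occupied = (result.snapshots >= 0).sum(axis=1).astype(float)  # (T+1,)
    out = np.zeros_like(supply)
    nz = occupied > 0
    out[nz] = supply[nz] / occupied[nz, None]
    return out


def stabilisation_time(result: RunResult, tol: float = 0.05) -> int:
    """Earliest timestep from which the composition stays near its final value.

    Uses the L1 distance between the land-use composition vector (shares per
    type plus unmanaged) at each timestep and at the final timestep; returns
    the first timestep after which the distance never exceeds ``tol``.
    """
    names = result.aft_names
    comps = np.array(
        [
            list(landuse_composition(result.snapshots[t], names).values())
            for t in range(result.timesteps + 1)
        ]
    )
    dist = np.abs(comps - comps[-1]).sum(axis=1)
    unstable = np.flatnonzero(dist > tol)
    return int(unstable.max() + 1) if unstable.size else 0


@dataclass(frozen=True)
class EnsembleSummary:
    """Cross-realisation summary of one experiment variant.

    ``mean_supply``/``sd_supply`` are per-timestep global ensemble statistics
    of shape ``(timesteps + 1, n_services)``; shares are final-timestep
    ensemble means per type (plus unmanaged).
    """

    mean_supply: np.ndarray
    sd_supply: np.ndarray
    final_shares: dict[str, float]
    steady_initial: int | None
    steady_post_change: int | None


def summarise_ensemble(results: Sequence[RunResult]) -> EnsembleSummary:
    """Envelope statistics, convergence timesteps and final composition."""
    if not results:
        raise ValueError("empty ensemble")
    supplies = np.stack([r.global_supply() for r in results])  # (N, T+1, S)
    mean = supplies.mean(axis=0)
    sd = supplies.std(axis=0, ddof=1) if len(results) > 1 else np.zeros_like(mean)
    names = results[0].aft_names
    comps = [landuse_composition(r.final_snapshot(), names) for r in results]
    final_shares = {
        key: float(np.mean([c[key] for c in comps])) for key in comps[0]
    }
    change = results[0].config.demand.change_timestep
    T = results[0].timesteps
    steady_initial = steady_post = None
    if len(results) >= 2:
        end_first = change if change is not None else T
        steady_initial = detect_steady_state(supplies, window=range(1, end_first + 1))
        if change is not None:
            steady_post = detect_steady_state(supplies, window=range(change + 1, T + 1))
    return EnsembleSummary(
        mean_supply=mean,
        sd_supply=sd,
        final_shares=final_shares,
        steady_initial=steady_initial,
        steady_post_change=steady_post,
    )
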