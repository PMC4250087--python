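"""Persistence of run results as delimited text.

Exported files (all comma-delimited with headers, coordinates 0-based with
x = column rightwards, y = row upwards):

- ``supplies.csv``     realisation, timestep, scope, service, demand, supply
                       (scope = region index, or "global" aggregate rows)
- ``events.csv``       realisation, timestep, event, x, y, aft, previous_aft,
                       plus the capitals of the affected cell
- ``snapshot_rXX_tYY.csv``  grid of type labels for recorded timesteps
                       (initial and final by default)
- ``summary.csv``      ensemble mean and dispersion of global supply
- ``demand_schedule.csv``  timestep, scope, service, demand
- ``manifest.json``    provenance (see :class:`landsim.config.RunManifest`)
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import SERVICES
from .config import RunManifest
from .engine import UNMANAGED, RunResult
from .market import DemandSchedule
from .metrics import summarise_ensemble

__all__ = ["export_demand_schedule", "export_run", "supplies_frame"]


def export_demand_schedule(schedule: DemandSchedule, path: str | Path) -> None:
    """Write a demand schedule as (timestep, scope, service, demand) rows."""
    rows = []
    for t in range(schedule.timesteps + 1):
        regional = schedule.regional(t)
        for r in range(schedule.n_regions):
            for s, svc in enumerate(SERVICES):
                rows.append((t, r, svc, regional[r, s]))
    pd.DataFrame(rows, columns=["timestep", "scope", "service", "demand"]).to_csv(
        path, index=False
    )


def supplies_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    """Long-format supply/demand table over an ensemble.

    One row per (realisation, timestep, scope, service); regional rows carry
    the region index as scope, and "global" rows the arena aggregate.
    """
    frames = []
    for i, res in enumerate(results):
        T, R, S = res.supply.shape
        t_idx, r_idx, s_idx = np.meshgrid(
            np.arange(T), np.arange(R), np.arange(S), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "realisation": i,
                    "timestep": t_idx.ravel(),
                    "scope": r_idx.ravel().astype(object),
                    "service": np.array(SERVICES)[s_idx.ravel()],
                    "demand": res.demand.ravel(),
                    "supply": res.supply.ravel(),
                }
            )
        )
        gt, gs = np.meshgrid(np.arange(T), np.arange(S), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "realisation": i,
                    "timestep": gt.ravel(),
                    "scope": "global",
                    "service": np.array(SERVICES)[gs.ravel()],
                    "demand": res.global_demand().ravel(),
                    "supply": res.global_supply().ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _events_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    rows = []
    for i, res in enumerate(results):
        world = res.config.world
        caps = {name: world.flat(name) for name in world.names}
        names = res.aft_names
        ev = res.events
        for t, kind, cell, aft, other in zip(
            ev.timestep, ev.kind, ev.cell, ev.aft, ev.other
        ):
            prev = ""
            if kind == "takeover":
                prev_idx = int(other)
                prev = "unmanaged" if prev_idx == UNMANAGED else names[prev_idx]
            rows.append(
                (
                    i,
                    t,
                    kind,
                    cell % world.width,
                    cell // world.width,
                    names[aft],
                    prev,
                    *(caps[name][cell] for name in world.names),
                )
            )
    cols = [
        "realisation",
        "timestep",
        "event",
        "x",
        "y",
        "aft",
        "previous_aft",
        *(f"capital_{name}" for name in results[0].config.world.names),
    ]
    return pd.DataFrame(rows, columns=cols)


def _write_snapshot(res: RunResult, t: int, path: Path) -> None:
    world = res.config.world
    labels = np.array([*res.aft_names, "unmanaged"], dtype=object)
    grid = labels[res.snapshots[t]].reshape(world.height, world.width)
    with path.open("w") as fh:
        fh.write(f"# width={world.width} height={world.height} timestep={t}\n")
        for y in range(world.height):
            fh.write(",".join(grid[y]) + "\n")


def export_run(
    results: Sequence[RunResult],
    manifest: RunManifest,
    out_dir: str | Path,
    snapshot_timesteps: Sequence[int] | None = None,
) -> list[str]:
    """Write an ensemble's outputs to ``out_dir``; returns the file inventory.

    ``snapshot_timesteps`` defaults to the initial and final timesteps of
    each realisation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: list[str] = []

    supplies_frame(results).to_csv(out / "supplies.csv", index=False)
    inventory.append("supplies.csv")

    _events_frame(results).to_csv(out / "events.csv", index=False)
    inventory.append("events.csv")

    T = results[0].timesteps
    snaps = list(snapshot_timesteps) if snapshot_timesteps is not None else [0, T]
    for i, res in enumerate(results):
        for t in snaps:
            name = f"snapshot_r{i:02d}_t{t:02d}.csv"
            _write_snapshot(res, t, out / name)
            inventory.append(name)

    summary = summarise_ensemble(results)
    rows = []
    for t in range(T + 1):
        for s, svc in enumerate(SERVICES):
            rows.append((t, svc, summary.mean_supply[t, s], summary.sd_supply[t, s]))
    pd.DataFrame(
        rows, columns=["timestep", "service", "mean_supply", "sd_supply"]
    ).to_csv(out / "summary.csv", index=False)
    inventory.append("summary.csv")

    export_demand_schedule(results[0].config.demand, out / "demand_schedule.csv")
    inventory.append("demand_schedule.csv")

    manifest.files = sorted(inventory)
    manifest.wall_clock.setdefault(
        "exported_at", datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    manifest.write(out / "manifest.json")
    inventory.append("manifest.json")
    return sorted(inventory)
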