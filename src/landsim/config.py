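"""Configuration files and run manifests.

A run is described by a small YAML document naming an experiment code and
optional overrides; everything else is derived deterministically, so a
manifest recording the code, overrides and base seed suffices to reproduce
every output bit-exactly (wall-clock metadata aside).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .experiments import ExperimentConfig, build_config

__all__ = ["RunManifest", "load_config", "save_config"]

_OVERRIDE_KEYS = {
    "width",
    "height",
    "timesteps",
    "n_reps",
    "base_seed",
    "headroom",
    "search_iterations",
    "cells_per_search",
}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration file.

    The file must name an ``experiment`` code; any other keys must be known
    overrides. A ``grid: WxH`` shorthand expands to width/height.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "experiment" not in raw:
        raise ValueError(f"{path}: missing required key 'experiment'")
    code = str(raw.pop("experiment"))
    if "grid" in raw:
        grid = str(raw.pop("grid"))
        try:
            w, h = (int(v) for v in grid.lower().split("x"))
        except ValueError:
            raise ValueError(f"{path}: grid must look like '60x60', got {grid!r}") from None
        raw["width"], raw["height"] = w, h
    unknown = set(raw) - _OVERRIDE_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return build_config(code, **raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a config file that :func:`load_config` round-trips exactly."""
    doc = {
        "experiment": cfg.code,
        "width": cfg.width,
        "height": cfg.height,
        "timesteps": cfg.timesteps,
        "n_reps": cfg.n_reps,
        "base_seed": cfg.base_seed,
        "headroom": cfg.headroom,
        "search_iterations": cfg.search_iterations,
        "cells_per_search": cfg.cells_per_search,
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance record written next to every exported run."""

    experiment: str
    overrides: dict[str, Any]
    base_seed: int
    n_reps: int
    realisation_seeds: list[int]
    version: str = __version__
    files: list[str] = field(default_factory=list)
    wall_clock: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
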