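"""Synthetic arena construction: capital surfaces and region partitions.

The simulated world is a rectangular grid of land-parcel cells. Each cell
carries a value in [0, 1] for each named *capital* — an endowment that scales
an agent's production of an ecosystem service. The default arena has two
capitals, crop productivity and natural (amenity) capital, both maximised on
the right-hand edge so that the most productive land is contested by all
agent types while the vertical variation of natural capital still separates
them spatially.

Coordinate convention (used in all exports): 0-based, ``x`` is the column
index increasing rightwards, ``y`` is the row index increasing upwards.
Arrays are stored with shape ``(height, width)`` and ``arr[y, x]`` addressing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "CROP",
    "NATURAL",
    "CapitalGrid",
    "GradientSpec",
    "RegionMap",
    "generate_capital_grids",
    "make_region_map",
    "read_capital_grid",
    "write_capital_grid",
]

#: Canonical capital names of the default arena.
CROP = "crop_productivity"
NATURAL = "natural_capital"


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of the default gradient construction.

    Crop productivity rises linearly from ``floor`` in the leftmost column to
    ``ceiling`` in the rightmost. Natural capital is the same horizontal
    gradient multiplied by a vertical factor rising linearly from
    ``vertical_floor`` at the bottom row to 1.0 at the top row, so its
    maximum also sits on the right edge but varies bottom-to-top.
    """

    floor: float = 0.05
    ceiling: float = 1.0
    vertical_floor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise ValueError(
                f"need 0 <= floor <= ceiling <= 1, got {self.floor}, {self.ceiling}"
            )
        if not (0.0 <= self.vertical_floor <= 1.0):
            raise ValueError(f"vertical_floor must be in [0, 1], got {self.vertical_floor}")


@dataclass(frozen=True)
class CapitalGrid:
    """Per-cell values of each named capital, all in [0, 1].

    ``capitals`` maps capital name to an array of shape ``(height, width)``.
    Capitals are static: they never change over the course of a run.
    """

    width: int
    height: int
    capitals: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.width}x{self.height}")
        for name, grid in self.capitals.items():
            if grid.shape != (self.height, self.width):
                raise ValueError(
                    f"capital {name!r} has shape {grid.shape}, expected "
                    f"({self.height}, {self.width})"
                )
            if np.any(grid < 0.0) or np.any(grid > 1.0):
                raise ValueError(f"capital {name!r} has values outside [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.capitals)

    def flat(self, name: str) -> np.ndarray:
        """Capital values as a flat vector; cell index = y * width + x."""
        return np.ascontiguousarray(self.capitals[name]).ravel()

    def cell_capitals(self, x: int, y: int) -> dict[str, float]:
        """All capital values at cell (x, y)."""
        return {name: float(grid[y, x]) for name, grid in self.capitals.items()}

    def iter_cells(self) -> Iterator[tuple[int, int]]:
        for y in range(self.height):
            for x in range(self.width):
                yield x, y


@dataclass(frozen=True)
class RegionMap:
    """Assignment of every cell to exactly one demand-accounting region.

    ``assignment`` has shape ``(height, width)`` with integer region indices
    in ``[0, n_regions)``. One region is the globalised arena; four equal
    quadrants are the regionalised default.
    """

    assignment: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        if self.assignment.ndim != 2:
            raise ValueError("region assignment must be a 2-D array")
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        vals = np.unique(self.assignment)
        if vals.min() < 0 or vals.max() >= self.n_regions:
            raise ValueError("region indices out of range")

    @property
    def flat(self) -> np.ndarray:
        return np.ascontiguousarray(self.assignment).ravel()

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.flat, minlength=self.n_regions)


def _horizontal_gradient(width: int, floor: float, ceiling: float) -> np.ndarray:
    # width 1 degenerates to the ceiling (the "right edge" is the only column)
    if width == 1:
        return np.array([ceiling])
    grad = floor + (ceiling - floor) * np.arange(width) / (width - 1)
    # guard against 1-ulp overshoot of the ceiling at the right edge
    return np.clip(grad, floor, ceiling)


def generate_capital_grids(
    width: int, height: int, spec: GradientSpec | None = None
) -> CapitalGrid:
    """Build the default two-capital arena.

    Crop productivity depends only on ``x``; natural capital is the same
    horizontal gradient modulated vertically so that both capitals peak in
    the rightmost column but natural capital additionally favours the top of
    the arena. Both surfaces are deterministic functions of the spec.
    """
    if width < 1 or height < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {width}x{height}")
    spec = spec or GradientSpec()
    grad = _horizontal_gradient(width, spec.floor, spec.ceiling)
    crop = np.tile(grad, (height, 1))
    if height == 1:
        vert = np.ones((1, 1))
    else:
        vert = (
            spec.vertical_floor
            + (1.0 - spec.vertical_floor) * np.arange(height) / (height - 1)
        )[:, None]
    natural = crop * vert
    return CapitalGrid(width=width, height=height, capitals={CROP: crop, NATURAL: natural})


def make_region_map(width: int, height: int, per_side: int) -> RegionMap:
    """Partition a ``width x height`` arena into ``per_side**2`` equal
    rectangular regions (``per_side=1`` is the globalised arena).

    Regions are indexed row-major over the region lattice, bottom-left first.
    """
    if per_side < 1:
        raise ValueError("per_side must be >= 1")
    if width % per_side or height % per_side:
        raise ValueError(
            f"per_side={per_side} must divide both width={width} and height={height}"
        )
    rw, rh = width // per_side, height // per_side
    ys, xs = np.mgrid[0:height, 0:width]
    assignment = (ys // rh) * per_side + (xs // rw)
    return RegionMap(assignment=assignment, n_regions=per_side * per_side)


def write_capital_grid(grid: CapitalGrid, name: str, path: str | Path) -> None:
    """Write one capital surface as a delimited text matrix.

    The header records width, height and the capital name; data rows follow
    row-major (row ``y=0`` first), comma-delimited.
    """
    arr = grid.capitals[name]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# width={grid.width} height={grid.height} capital={name}\n")
        for y in range(grid.height):
            fh.write(",".join(f"{v:.10g}" for v in arr[y]) + "\n")


def read_capital_grid(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a capital surface written by :func:`write_capital_grid`.

    Returns the capital name and the ``(height, width)`` array.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing header line")
        fields = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        rows = [
            np.array([float(v) for v in line.split(",")]) for line in fh if line.strip()
        ]
    arr = np.vstack(rows)
    expect = (int(fields["height"]), int(fields["width"]))
    if arr.shape != expect:
        raise ValueError(f"{path}: data shape {arr.shape} does not match header {expect}")
    return fields["capital"], arr
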