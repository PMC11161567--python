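"""Grid-based distribution ranges and the three-way overlap classification.

A species' range is the set of grid cells containing at least one retained
occurrence (cells, not hulls: the 50 % rule is then well defined). Two
ranges are *sympatric* when either is covered >= 50 % by the other,
*allopatric* when they share no cell, and *parapatric* otherwise. The
default cell size of 0.01 degrees (~1 km) matches typical environmental
raster resolution and is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["OccupancyRange", "OverlapClass", "occupancy_cells", "classify_overlap"]

DEFAULT_CELL_SIZE = 0.01  # degrees, ~1 km


def _cell_index(x: float, y: float, cell: float,
                origin: tuple[float, float]) -> tuple[int, int]:
    # same half-open convention as RasterGrid: [x, x+d) x (y-d, y]
    x0, y0 = origin
    col = math.floor((x - x0) / cell)
    ry = (y0 - y) / cell
    row = 0 if ry == 0 else math.floor(ry)
    return row, col


@dataclass(frozen=True)
class OccupancyRange:
    species: str
    cells: frozenset[tuple[int, int]]
    cell_size: float = DEFAULT_CELL_SIZE

    def __len__(self) -> int:
        return len(self.cells)


def occupancy_cells(
    records: pd.DataFrame,
    cell_size: float = DEFAULT_CELL_SIZE,
    origin: tuple[float, float] = (0.0, 0.0),
    species: str | None = None,
) -> OccupancyRange:
    """Occupied-cell set for one species' cleaned records."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if species is not None and "species" in records.columns:
        records = records[records["species"] == species]
    name = species or (records["species"].iloc[0] if len(records) else "?")
    if len(records) == 0:
        raise ValueError(f"no records for species {name!r}")
    cells = frozenset(
        _cell_index(x, y, cell_size, origin)
        for x, y in zip(records["lon"].to_numpy(dtype=float),
                        records["lat"].to_numpy(dtype=float))
    )
    return OccupancyRange(name, cells, cell_size)


def pooled_range(ranges: Iterable[OccupancyRange], name: str = "pooled") -> OccupancyRange:
    """Union of several species' occupied cells (pair-side pooling)."""
    ranges = list(ranges)
    sizes = {r.cell_size for r in ranges}
    if len(sizes) > 1:
        raise ValueError("cannot pool ranges with different cell sizes")
    cells = frozenset().union(*(r.cells for r in ranges))
    return OccupancyRange(name, cells, ranges[0].cell_size)


@dataclass(frozen=True)
class OverlapClass:
    klass: str  # sympatric | parapatric | allopatric
    f_a: float  # |A n B| / |A|
    f_b: float  # |A n B| / |B|


def classify_overlap(a: OccupancyRange, b: OccupancyRange,
                     sympatry_threshold: float = 0.5) -> OverlapClass:
    """Classify two nonempty ranges.

    Allopatric when the intersection is empty; sympatric when the range of
    one species is covered at least ``sympatry_threshold`` by the other
    (either direction suffices); parapatric otherwise.
    """
    if not a.cells or not b.cells:
        raise ValueError("both ranges must be nonempty")
    inter = len(a.cells & b.cells)
    f_a = inter / len(a.cells)
    f_b = inter / len(b.cells)
    if inter == 0:
        klass = "allopatric"
    elif max(f_a, f_b) >= sympatry_threshold:
        klass = "sympatric"
    else:
        klass = "parapatric"
    return OverlapClass(klass, f_a, f_b)
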