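"""Occurrence-record cleaning and raster value extraction.

Occurrence tables are pandas DataFrames with columns ``species``, ``lon``,
``lat`` (WGS84 decimal degrees), ``year`` (nullable int), ``uncertainty_m``
(nullable float) and ``source``. The cleaner applies the standard
biodiversity-data hygiene rules — zero coordinates, coordinate uncertainty
above 100 km, records collected before 1945 (pre-dating usable
geo-localization), exact per-species coordinate duplicates, and any
caller-supplied geographic masks (marine areas, institution/centroid
buffers, native-range polygons) — and returns both the kept records and a
per-record verdict report: nothing is ever silently dropped.

Rasters are regular lon/lat grids held as :class:`RasterGrid`; the ESRI
ASCII grid format is read and written directly (it is a six-line-header
plain-text format). Cell membership uses half-open cells
``[x, x+dx) x (y-dy, y]`` so that every point belongs to exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OCCURRENCE_COLUMNS",
    "read_occurrences",
    "clean_occurrences",
    "RasterGrid",
    "extract_env",
    "TraitTable",
    "species_trait_table",
]

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "year", "uncertainty_m", "source"]

# GBIF/DarwinCore-style column aliases accepted on input
_ALIASES = {
    "decimallongitude": "lon",
    "decimallatitude": "lat",
    "coordinateuncertaintyinmeters": "uncertainty_m",
}


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, mapping DarwinCore column names onto the
    internal schema and leaving values unparsed-but-flagged to the cleaner."""
    df = pd.read_csv(path)
    df.columns = [_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    for col in OCCURRENCE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "source" else ""
    return df[OCCURRENCE_COLUMNS]


def clean_occurrences(
    records: pd.DataFrame,
    max_uncertainty_m: float = 100_000.0,
    min_year: int = 1945,
    masks: Mapping[str, Callable[[float, float], bool]] | None = None,
    duplicate_decimals: int | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cleaning filters; return ``(kept, report)``.

    The report has one row per input record with its verdict flag:
    ``kept``, ``invalid`` (unparseable/out-of-range coordinates),
    ``zero-coordinate``, ``uncertainty``, ``pre-{min_year}``,
    ``mask:<name>`` or ``duplicate`` (first occurrence kept). Records with
    absent year or uncertainty pass those filters unless ``strict``.
    Coordinates are never altered. ``duplicate_decimals`` optionally rounds
    coordinates before duplicate comparison (exact equality by default).
    """
    records = records.reset_index(drop=True)
    n = len(records)
    flags = np.array(["kept"] * n, dtype=object)

    lon = pd.to_numeric(records.get("lon"), errors="coerce")
    lat = pd.to_numeric(records.get("lat"), errors="coerce")
    year = pd.to_numeric(records.get("year"), errors="coerce")
    unc = pd.to_numeric(records.get("uncertainty_m"), errors="coerce")

    bad_coord = (lon.isna() | lat.isna()
                 | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    # distinguish "present but unparseable" from genuinely absent
    raw_present = records["lon"].notna() & records["lat"].notna()
    flags[(bad_coord & raw_present).to_numpy()] = "invalid"
    flags[(bad_coord & ~raw_present).to_numpy()] = "invalid"

    live = flags == "kept"
    zero = ((lon == 0) | (lat == 0)).to_numpy() & live
    flags[zero] = "zero-coordinate"

    live = flags == "kept"
    too_vague = np.where(unc.isna(), strict, unc > max_uncertainty_m) & live
    flags[too_vague] = "uncertainty"

    live = flags == "kept"
    old = np.where(year.isna(), strict, year < min_year) & live
    flags[old] = f"pre-{min_year}"

    if masks:
        for name, inside in masks.items():
            live = flags == "kept"
            for i in np.nonzero(live)[0]:
                if inside(float(lon.iloc[i]), float(lat.iloc[i])):
                    flags[i] = f"mask:{name}"

    # per-species exact coordinate duplicates, first kept
    seen: set[tuple] = set()
    for i in range(n):
        if flags[i] != "kept":
            continue
        x, y = float(lon.iloc[i]), float(lat.iloc[i])
        if duplicate_decimals is not None:
            x, y = round(x, duplicate_decimals), round(y, duplicate_decimals)
        key = (records["species"].iloc[i], x, y)
        if key in seen:
            flags[i] = "duplicate"
        else:
            seen.add(key)

    report = records.copy()
    report["flag"] = flags
    kept = records[flags == "kept"].copy()
    kept["lon"] = lon[flags == "kept"]
    kept["lat"] = lat[flags == "kept"]
    return kept, report


def thin_to_grid(records: pd.DataFrame, cell_size: float,
                 origin: tuple[float, float] = (0.0, 0.0)) -> pd.DataFrame:
    """Optional aggregation step: keep one record per species per grid cell
    (the first), emulating occurrence sets pre-aggregated to a fixed
    resolution. Off by default in every pipeline; apply explicitly."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    x0, y0 = origin
    col = np.floor((records["lon"].to_numpy(dtype=float) - x0) / cell_size)
    ry = (y0 - records["lat"].to_numpy(dtype=float)) / cell_size
    row = np.where(ry == 0, 0, np.floor(ry))
    key = pd.DataFrame({"species": records["species"], "row": row, "col": col})
    return records[~key.duplicated()].copy()


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """Regular grid: ``origin`` is the (x, y) outer corner of cell (0, 0),
    i.e. the top-left corner; rows increase southwards."""
    origin: tuple[float, float]
    cell: float
    values: np.ndarray  # shape (nrows, ncols)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.values.ndim != 2:
            raise ValueError("value matrix must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the half-open cell [x, x+d) x (y-d, y] containing the
        point, or None when outside the extent."""
        x0, y0 = self.origin
        col = math.floor((x - x0) / self.cell)
        ry = (y0 - y) / self.cell
        # row r spans (y0-(r+1)d, y0-r*d]; floor puts a shared-edge point in
        # the cell whose top edge it is, except the top boundary y0 itself
        row = 0 if ry == 0 else math.floor(ry)
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def value_at(self, x: float, y: float) -> float:
        """Value of the containing cell; NaN when out of extent or nodata."""
        idx = self.cell_of(x, y)
        if idx is None:
            return float("nan")
        v = self.values[idx]
        return float("nan") if v == self.nodata else float(v)

    # -- ESRI ASCII grid ---------------------------------------------------
    @classmethod
    def from_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"):
                    header[key] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
        values = np.array(rows)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        if values.shape != (nrows, ncols):
            raise ValueError(
                f"grid body {values.shape} does not match header "
                f"({nrows}, {ncols})")
        cell = header["cellsize"]
        origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
        return cls(origin, cell, values, header.get("nodata_value", -9999.0))

    def to_ascii(self, path) -> None:
        x0, y0 = self.origin
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\nnrows {self.nrows}\n")
            fh.write(f"xllcorner {x0:.10g}\n")
            fh.write(f"yllcorner {y0 - self.nrows * self.cell:.10g}\n")
            fh.write(f"cellsize {self.cell:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def extract_env(records: pd.DataFrame, grid: RasterGrid) -> tuple[np.ndarray, list[str]]:
    """Point-in-cell raster extraction (no interpolation).

    Returns values aligned to the records (NaN where absent) and a status
    flag per record: ``ok``, ``out-of-extent`` or ``nodata``.
    """
    values = np.full(len(records), np.nan)
    status: list[str] = []
    for i, (x, y) in enumerate(zip(records["lon"].to_numpy(dtype=float),
                                   records["lat"].to_numpy(dtype=float))):
        idx = grid.cell_of(x, y)
        if idx is None:
            status.append("out-of-extent")
            continue
        v = grid.values[idx]
        if v == grid.nodata:
            status.append("nodata")
            continue
        values[i] = v
        status.append("ok")
    return values, status


# ---------------------------------------------------------------------------
# Per-species trait vectors
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-species vectors of occurrence-level environmental values, one
    vector per variable (e.g. precipitation in mm/yr, elevation in m)."""
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def species(self) -> list[str]:
        return sorted(self.data)

    def values(self, species: str, variable: str) -> np.ndarray:
        return self.data.get(species, {}).get(variable, np.array([]))

    def mean(self, species: str, variable: str) -> float:
        v = self.values(species, variable)
        return float(np.mean(v)) if v.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sp, var, float(v))
            for sp, variables in sorted(self.data.items())
            for var, vec in sorted(variables.items())
            for v in vec
        ]
        return pd.DataFrame(rows, columns=["species", "variable", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        table = cls()
        for (sp, var), grp in df.groupby(["species", "variable"]):
            table.data.setdefault(sp, {})[var] = grp["value"].to_numpy(dtype=float)
        return table


def species_trait_table(
    records: pd.DataFrame,
    variables: Mapping[str, np.ndarray],
) -> tuple[TraitTable, list[str]]:
    """Group record-aligned extracted values into per-species vectors,
    dropping absent (NaN) values; species with zero usable values for any
    variable are listed in the returned warning report."""
    table = TraitTable()
    empty: list[str] = []
    species = records["species"].to_numpy()
    for var, vals in variables.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) != len(records):
            raise ValueError(f"values for {var!r} not aligned to records")
        for sp in np.unique(species):
            v = vals[species == sp]
            v = v[~np.isnan(v)]
            table.data.setdefault(sp, {})[var] = v
            if v.size == 0:
                empty.append(f"{sp}:{var}")
    return table, sorted(set(empty))
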