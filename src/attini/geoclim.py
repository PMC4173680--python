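"""Per-species environmental covariates from gridded climate layers.

Grids are regular geographic lat/lon rasters stored as plain text with a
small header (ncols, nrows, cellsize_arcmin, xll, yll, nodata) followed by
rows of cell values, the first row being the northernmost.  Localities with
a stated precision coarser than 20 km^2 are discarded as uninformative;
grids are block-mean aggregated to a common 10-arcmin lattice before
extraction so a locality maps to one cell.  Cell membership uses half-open
cells [west, east) x [south, north); longitudes on the seam of a global
grid wrap east.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLIMATE_VARIABLES = (
    "diurnal_temperature_range",
    "isothermality",
    "temperature_seasonality",
    "precipitation_seasonality",
)

__all__ = [
    "ClimateGrid",
    "CLIMATE_VARIABLES",
    "filter_localities",
    "resample_grid",
    "species_environment_means",
    "read_grid",
    "write_grid",
]


@dataclass
class ClimateGrid:
    """A single-variable regular lat/lon grid (row 0 = northernmost)."""

    name: str
    values: np.ndarray
    cellsize_arcmin: float
    xll: float  # west edge, decimal degrees
    yll: float  # south edge, decimal degrees
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize_arcmin <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_deg(self) -> float:
        return self.cellsize_arcmin / 60.0

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the half-open cell containing a point, or raise."""
        cs = self.cell_deg
        col = int(np.floor((lon - self.xll) / cs))
        if col == self.ncols and abs(self.ncols * cs - 360.0) < 1e-9:
            col = 0  # global seam wraps east
        row_s = int(np.floor((lat - self.yll) / cs))
        if not (0 <= col < self.ncols and 0 <= row_s < self.nrows):
            raise ValueError(f"point ({lat}, {lon}) outside grid {self.name}")
        return self.nrows - 1 - row_s, col

    def value_at(self, lat: float, lon: float) -> float | None:
        """Cell value at a point; None for a missing cell."""
        r, c = self.cell_of(lat, lon)
        v = self.values[r, c]
        return None if v == self.nodata or np.isnan(v) else float(v)


def filter_localities(localities: pd.DataFrame, max_area_km2: float = 20.0):
    """Drop localities stated at an area coarser than ``max_area_km2``.

    Expects columns species, lat, lon and optionally
    locality_precision_km2; records without a stated precision are kept.
    Invalid coordinates are rejected.  Returns ``(kept, log)`` with one log
    row per dropped record and its reason.
    """
    kept_rows, log = [], []
    for i, row in localities.iterrows():
        lat, lon = row["lat"], row["lon"]
        if pd.isna(lat) or pd.isna(lon) or not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
            log.append({"index": i, "species": row.get("species"),
                        "reason": f"invalid coordinates ({lat}, {lon})"})
            continue
        prec = row.get("locality_precision_km2", np.nan)
        if not pd.isna(prec) and prec > max_area_km2:
            log.append({"index": i, "species": row.get("species"),
                        "reason": f"precision {prec} km2 > {max_area_km2} km2"})
            continue
        kept_rows.append(i)
    return localities.loc[kept_rows], pd.DataFrame(log)


def resample_grid(grid: ClimateGrid, target_arcmin: float = 10.0,
                  method: str = "mean") -> ClimateGrid:
    """Aggregate to a coarser lattice whose cell size is an integer
    multiple of the source's.

    ``mean`` averages the block ignoring missing cells (all-missing blocks
    stay missing); ``nearest`` picks the block's top-left source cell.
    """
    ratio = target_arcmin / grid.cellsize_arcmin
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError(
            f"target {target_arcmin}' is not an integer multiple of "
            f"{grid.cellsize_arcmin}'")
    if f == 1:
        return ClimateGrid(grid.name, grid.values.copy(), grid.cellsize_arcmin,
                           grid.xll, grid.yll, grid.nodata)
    if grid.nrows % f or grid.ncols % f:
        raise ValueError("grid extent is not divisible by the block size")
    v = grid.values.copy()
    v[v == grid.nodata] = np.nan
    blocks = v.reshape(grid.nrows // f, f, grid.ncols // f, f)
    if method == "mean":
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out = np.nanmean(blocks, axis=(1, 3))
    elif method == "nearest":
        out = blocks[:, 0, :, 0]
    else:
        raise ValueError("method must be 'mean' or 'nearest'")
    out = np.where(np.isnan(out), grid.nodata, out)
    return ClimateGrid(grid.name, out, target_arcmin, grid.xll, grid.yll,
                       grid.nodata)


def species_environment_means(localities: pd.DataFrame, grids) -> pd.DataFrame:
    """Average each climate variable over a species' locality cells.

    All grids must share one lattice.  Each retained locality contributes
    the value of its containing cell; localities outside a grid or in
    missing cells are skipped with a warning column in the result's attrs.
    A mean latitude column is always included.  Species with no usable
    locality are absent from the output.
    """
    grids = list(grids)
    lattices = {(g.cellsize_arcmin, g.xll, g.yll, g.nrows, g.ncols) for g in grids}
    if len(lattices) > 1:
        raise ValueError("grids are not on a common lattice; resample first")
    records: dict[str, dict[str, list[float]]] = {}
    skipped = []
    for _, row in localities.iterrows():
        sp, lat, lon = row["species"], float(row["lat"]), float(row["lon"])
        vals = {}
        ok = True
        for g in grids:
            try:
                v = g.value_at(lat, lon)
            except ValueError:
                skipped.append({"species": sp, "lat": lat, "lon": lon,
                                "reason": "outside grid"})
                ok = False
                break
            if v is None:
                skipped.append({"species": sp, "lat": lat, "lon": lon,
                                "reason": f"missing cell in {g.name}"})
                ok = False
                break
            vals[g.name] = v
        if not ok:
            continue
        store = records.setdefault(sp, {g.name: [] for g in grids} | {"latitude": []})
        for k, v in vals.items():
            store[k].append(v)
        store["latitude"].append(lat)
    rows = []
    for sp in sorted(records):
        row = {"species": sp}
        for k, vals in records[sp].items():
            row[k] = float(np.mean(vals))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("species") if rows else pd.DataFrame()
    out.attrs["skipped"] = pd.DataFrame(skipped)
    return out


def write_grid(grid: ClimateGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\nnrows {grid.nrows}\n")
        fh.write(f"cellsize_arcmin {grid.cellsize_arcmin:g}\n")
        fh.write(f"xll {grid.xll:g}\nyll {grid.yll:g}\nnodata {grid.nodata:g}\n")
        np.savetxt(fh, grid.values, fmt="%.6g")


def read_grid(path, name: str | None = None) -> ClimateGrid:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    import os
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
        name = name.removeprefix("grid_")
    return ClimateGrid(name, values, header["cellsize_arcmin"],
                       header["xll"], header["yll"], header.get("nodata", -9999.0))
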