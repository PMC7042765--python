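"""Occurrence and raster ingestion, rarefaction, background sampling, collinearity filter.

Rasters are plain-text ESRI ASCII grids, one predictor per file, all sharing a
grid (shape, lower-left corner, cell size).  Coordinates are WGS84 decimal
degrees, rasters north-up (row 0 = northernmost row).  A cell with upper-left
corner (x, y) covers the half-open box [x, x+d) in longitude and (y-d, y] in
latitude, and points are assigned to cells by floor arithmetic on that
convention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "EnvStack",
    "VariableSelection",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "read_occurrences",
    "rarefy",
    "sample_background",
    "extract_env",
    "select_variables",
]


@dataclass
class OccurrenceSet:
    """Georeferenced presence (or background) points for one range.

    ``env`` holds one row of predictor values per point once
    :func:`extract_env` has run; before that it is ``None``.
    """

    range_label: str
    lon: np.ndarray
    lat: np.ndarray
    env: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat must have equal length")
        if self.env is not None and len(self.env) != len(self.lon):
            raise ValueError("env row count must equal point count")

    def __len__(self) -> int:
        return self.lon.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.column_stack([self.lon, self.lat])

    def subset(self, index: np.ndarray) -> "OccurrenceSet":
        env = self.env.iloc[index].reset_index(drop=True) if self.env is not None else None
        return OccurrenceSet(self.range_label, self.lon[index], self.lat[index], env)

    def to_csv(self, path: str | Path, species: str = "species") -> None:
        df = pd.DataFrame({"species": species, "lon": self.lon, "lat": self.lat})
        if self.env is not None:
            df = pd.concat([df, self.env.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)


@dataclass
class EnvStack:
    """Aligned multi-variable raster stack plus accessible-area mask.

    Parameters
    ----------
    layers : dict of name -> 2-D float array, all identically shaped.
    mask : boolean array, True = accessible cell. Every masked-in cell must
        have finite values in all layers.
    xll, yll : lower-left corner of the grid (degrees).
    cell_size : cell edge length (degrees).
    """

    layers: dict[str, np.ndarray]
    mask: np.ndarray
    xll: float
    yll: float
    cell_size: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        shapes = {name: a.shape for name, a in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"layer shapes differ: {shapes}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape must equal layer shape")
        bad = [
            name
            for name, a in self.layers.items()
            if not np.all(np.isfinite(np.asarray(a)[self.mask]))
        ]
        if bad:
            raise ValueError(f"non-finite values inside mask in layers: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    # -- grid geometry -----------------------------------------------------

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; -1 where outside the extent."""
        nrows, ncols = self.shape
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        col = np.floor((lon - self.xll) / self.cell_size).astype(int)
        ytop = self.yll + nrows * self.cell_size
        r = (ytop - lat) / self.cell_size
        row = np.floor(r).astype(int)
        # top edge of the grid belongs to row 0 (cells are (y-d, y] in latitude)
        row[np.isclose(lat, ytop)] = 0
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nrows = self.shape[0]
        lon = self.xll + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.yll + (nrows - np.asarray(row) - 0.5) * self.cell_size
        return lon, lat

    def values_at(self, row: np.ndarray, col: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({name: a[row, col] for name, a in self.layers.items()})

    def env_table(self, names: list[str] | None = None) -> pd.DataFrame:
        """Predictor values of all masked-in cells, one row per cell (row-major order)."""
        names = names or self.names
        return pd.DataFrame({n: self.layers[n][self.mask] for n in names})

    def select(self, names: list[str]) -> "EnvStack":
        return EnvStack(
            {n: self.layers[n] for n in names},
            self.mask,
            self.xll,
            self.yll,
            self.cell_size,
            self.crs,
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.xll, self.yll, self.cell_size)
        write_ascii_grid(
            directory / "mask.asc", self.mask.astype(float), self.xll, self.yll, self.cell_size
        )


@dataclass
class VariableSelection:
    """Outcome of the greedy pairwise-correlation filter."""

    cutoff: float
    kept: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"cutoff": self.cutoff, "kept": self.kept, "dropped": self.dropped}, indent=2
            )
        )


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float, float]:
    """Read an ESRI ASCII grid.

    Returns ``(array, xll, yll, cell_size, nodata)`` with no-data cells set to
    NaN.  Both ``xllcorner`` and ``xllcenter`` header conventions are accepted.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "xllcenter",
            "yllcenter",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required ASCII-grid header field '{key}'")
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:
        xll, yll = header["xllcenter"] - cs / 2, header["yllcenter"] - cs / 2
    nodata = header.get("nodata_value", -9999.0)
    arr = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {arr.shape} does not match header")
    arr[arr == nodata] = np.nan
    return arr, xll, yll, cs, nodata


def write_ascii_grid(
    path: str | Path,
    arr: np.ndarray,
    xll: float,
    yll: float,
    cell_size: float,
    nodata: float = -9999.0,
) -> None:
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.10g")


def read_stack(
    layer_paths: dict[str, str | Path],
    mask_path: str | Path | None = None,
    crs: str = "EPSG:4326",
) -> EnvStack:
    """Assemble an :class:`EnvStack` from per-variable ASCII grids.

    All grids must share shape, corner and cell size.  If ``mask_path`` is
    omitted the mask is every cell with finite values in all layers; otherwise
    the 0/1 mask raster is intersected with that finite-value set.
    """
    layers: dict[str, np.ndarray] = {}
    geo: tuple[float, float, float] | None = None
    for name, p in layer_paths.items():
        arr, xll, yll, cs, _ = read_ascii_grid(p)
        if geo is None:
            geo = (xll, yll, cs)
        elif not np.allclose(geo, (xll, yll, cs)):
            raise ValueError(f"layer '{name}' grid does not align with the first layer")
        layers[name] = arr
    assert geo is not None
    finite = np.logical_and.reduce([np.isfinite(a) for a in layers.values()])
    if mask_path is not None:
        m, xll, yll, cs, _ = read_ascii_grid(mask_path)
        if not np.allclose(geo, (xll, yll, cs)) or m.shape != finite.shape:
            raise ValueError("mask grid does not align with the layers")
        mask = finite & (np.nan_to_num(m) > 0)
    else:
        mask = finite
    return EnvStack(layers, mask, *geo, crs)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------


def read_occurrences(
    path: str | Path,
    range_label: str,
    lon_col: str = "lon",
    lat_col: str = "lat",
    species_col: str = "species",
) -> OccurrenceSet:
    """Read presence records from a CSV with species / longitude / latitude columns.

    Rows with non-numeric or non-finite coordinates are skipped with a log
    entry; duplicate coordinates are retained (rarefaction is a separate
    step) and row order is preserved.

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    df = pd.read_csv(path)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column '{col}' not found (have {list(df.columns)})")
    if species_col not in df.columns:
        logger.warning("%s: no '%s' column; proceeding without species names", path, species_col)
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = np.isfinite(lon) & np.isfinite(lat)
    n_bad = int((~ok).sum())
    if n_bad:
        for i in df.index[~ok]:
            logger.info(
                "%s row %d skipped: non-numeric coordinate (%r, %r)",
                path,
                i,
                df[lon_col][i],
                df[lat_col][i],
            )
        logger.warning("%s: skipped %d rows with invalid coordinates", path, n_bad)
    return OccurrenceSet(range_label, lon[ok].to_numpy(), lat[ok].to_numpy())


def rarefy(occ: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Spatially rarefy to at most one point per raster cell.

    The retained point per cell is the first in input order.  Points outside
    the raster extent are dropped with a log entry.  The rarefaction grid is
    the predictor grid itself (at 30 arc-seconds one cell is roughly 1 km²).
    """
    if len(occ) == 0:
        return occ
    row, col = stack.cell_index(occ.lon, occ.lat)
    inside = row >= 0
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("rarefy[%s]: dropped %d points outside raster extent", occ.range_label, n_out)
    cell = row.astype(np.int64) * stack.shape[1] + col
    keep = inside & ~pd.Series(cell).duplicated().to_numpy()
    return occ.subset(np.flatnonzero(keep))


def sample_background(
    stack: EnvStack, n: int, seed: int | np.random.Generator | None = None
) -> OccurrenceSet:
    """Draw ``n`` background points uniformly from masked-in cell centers.

    Sampling is without replacement when ``n`` does not exceed the number of
    accessible cells, otherwise with replacement (with a warning).  Points
    carry their predictor vectors directly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows, cols = np.nonzero(stack.mask)
    if rows.size == 0:
        raise ValueError("empty accessible-area mask: no background can be sampled")
    replace = n > rows.size
    if replace:
        warnings.warn(
            f"requested {n} background points from {rows.size} accessible cells; "
            "sampling with replacement",
            stacklevel=2,
        )
    idx = rng.choice(rows.size, size=n, replace=replace)
    lon, lat = stack.cell_center(rows[idx], cols[idx])
    env = stack.values_at(rows[idx], cols[idx])
    return OccurrenceSet("background", lon, lat, env)


def extract_env(occ: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Attach predictor values to each point by nearest-cell lookup.

    Points falling on masked-out or no-data cells (or outside the extent) are
    removed with a log entry.
    """
    row, col = stack.cell_index(occ.lon, occ.lat)
    ok = row >= 0
    ok[ok] &= stack.mask[row[ok], col[ok]]
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning(
            "extract_env[%s]: removed %d points on masked-out or no-data cells",
            occ.range_label,
            n_drop,
        )
    out = occ.subset(np.flatnonzero(ok))
    out.env = stack.values_at(row[ok], col[ok]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# collinearity filter
# ---------------------------------------------------------------------------


def select_variables(
    sample: pd.DataFrame,
    cutoff: float = 0.75,
    priority: list[str] | None = None,
) -> VariableSelection:
    """Greedy low-collinearity variable subset at a |Pearson r| cutoff.

    Variables are visited in ``priority`` order (default: column order); a
    candidate is dropped as soon as its absolute Pearson correlation with any
    already-kept variable exceeds ``cutoff``.  Zero-variance variables are
    dropped with reason ``"zero variance"``.
    """
    if sample.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    if len(sample) < 10:
        raise ValueError("need at least 10 sample rows to estimate correlations")
    order = list(priority) if priority else list(sample.columns)
    missing = set(order) - set(sample.columns)
    if missing:
        raise ValueError(f"priority names not in sample: {sorted(missing)}")
    order += [c for c in sample.columns if c not in order]

    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for name in order:
        x = sample[name].to_numpy(float)
        if np.std(x) == 0:
            dropped.append((name, "zero variance"))
            continue
        clash = None
        for k in kept:
            r = np.corrcoef(x, sample[k].to_numpy(float))[0, 1]
            if abs(r) > cutoff:
                clash = k
                break
        if clash is None:
            kept.append(name)
        else:
            dropped.append((name, clash))
    return VariableSelection(cutoff=cutoff, kept=kept, dropped=dropped)
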