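"""Lightweight geographic raster containers and plain-text grid I/O.

Rasters are stored as 2-D masked lattices on an equirectangular
(plate carrée) grid in decimal degrees, row 0 at the northern edge.
Files are read and written as ESRI ASCII grids (``.asc``), a plain-text
format of six header lines followed by the value matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridTransform:
    """Geographic placement of a raster: west/north origin and square cell size (degrees)."""

    west: float
    north: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell [row, col]."""
        lon = self.west + (col + 0.5) * self.cellsize
        lat = self.north - (row + 0.5) * self.cellsize
        return lon, lat

    def index_of(self, lon: float, lat: float, shape: tuple[int, int]) -> tuple[int, int] | None:
        """Nearest-cell (row, col) containing the point, or None if outside the extent."""
        col = int(math.floor((lon - self.west) / self.cellsize))
        row = int(math.floor((self.north - lat) / self.cellsize))
        nrows, ncols = shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None


@dataclass
class RasterGrid:
    """A single raster layer: values with a missing-data mask and a geographic transform."""

    values: np.ndarray
    transform: GridTransform
    mask: np.ndarray | None = None  # True where data are MISSING
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        """Boolean array, True where data are present."""
        return ~self.mask


@dataclass
class PredictorStack:
    """Aligned, named climate layers sharing one transform, shape and mask domain.

    ``latent`` optionally carries the generative 2-D environment fields of a
    synthetic scenario so that truth-aware tests can evaluate suitability.
    """

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    latent: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.layers.values()}
        transforms = {g.transform for g in self.layers.values()}
        if len(shapes) > 1 or len(transforms) > 1:
            raise ValueError("all layers must share shape and transform")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def transform(self) -> GridTransform:
        return next(iter(self.layers.values())).transform

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers:
            if grid.shape != self.shape or grid.transform != self.transform:
                raise ValueError("layer is not aligned with the stack")
        self.layers[name] = grid

    def subset(self, names: Iterable[str]) -> "PredictorStack":
        return PredictorStack({n: self.layers[n] for n in names}, latent=self.latent)

    def combined_valid(self) -> np.ndarray:
        """Cells valid in every layer."""
        out = np.ones(self.shape, dtype=bool)
        for g in self.layers.values():
            out &= g.valid()
        return out

    def to_matrix(self, valid_only: bool = True) -> np.ndarray:
        """Cells × layers matrix, restricted to the combined valid mask."""
        arrs = [g.values.ravel() for g in self.layers.values()]
        m = np.column_stack(arrs)
        if valid_only:
            m = m[self.combined_valid().ravel()]
        return m


def read_ascii_grid(path: str | Path, nodata_default: float = -9999.0) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:], dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", nodata_default)
    mask = values == nodata
    vals = np.where(mask, np.nan, values)
    cellsize = header["cellsize"]
    transform = GridTransform(
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * cellsize,
        cellsize=cellsize,
    )
    return RasterGrid(vals, transform, mask=mask)


def write_ascii_grid(grid: RasterGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a RasterGrid as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    nrows, ncols = grid.shape
    t = grid.transform
    vals = np.where(grid.mask, nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.west:.10g}\n")
        fh.write(f"yllcorner {t.north - nrows * t.cellsize:.10g}\n")
        fh.write(f"cellsize {t.cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, vals, fmt="%.8g")


def write_stack(stack: PredictorStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack as ``<name>.asc`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(grid, p)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, names: Iterable[str] | None = None) -> PredictorStack:
    """Read ``<name>.asc`` layers from a directory into a PredictorStack."""
    directory = Path(directory)
    if names is None:
        names = sorted(p.stem for p in directory.glob("*.asc"))
    stack = PredictorStack()
    for name in names:
        stack.add(name, read_ascii_grid(directory / f"{name}.asc"))
    return stack


def cell_area_km2(transform: GridTransform, row: int, nrows: int) -> float:
    """Spherical area of one cell in a given row: R^2 * dlon * (sin(lat_top) - sin(lat_bot))."""
    lat_top = transform.north - row * transform.cellsize
    lat_bot = lat_top - transform.cellsize
    dlon = math.radians(transform.cellsize)
    return (
        EARTH_RADIUS_KM**2
        * dlon
        * (math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bot)))
    )


def cell_areas_km2(transform: GridTransform, shape: tuple[int, int]) -> np.ndarray:
    """Per-cell spherical areas (km^2) for the whole grid; constant along rows."""
    nrows, ncols = shape
    col = np.array([cell_area_km2(transform, r, nrows) for r in range(nrows)])
    return np.repeat(col[:, None], ncols, axis=1)
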