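"""Gridded environmental layers and presence records.

Rasters are co-registered single-band grids sharing shape, cell size, origin
and a validity mask, read and written as ESRI ASCII grids (a plain-text
format understood by every GIS). Coordinates are in map units; a point maps
to the cell containing it under the half-open convention: a point on a
shared edge belongs to the cell whose origin-side (left/bottom) edge it
touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class RasterStack:
    """p named layers on one grid with a shared validity mask.

    data: (p, rows, cols) float array; mask: True where cells are valid;
    xllcorner/yllcorner: map coordinates of the grid's lower-left corner;
    row 0 is the *top* row (ESRI convention).
    """

    names: list[str]
    data: np.ndarray
    mask: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (layers, rows, cols)")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per layer required")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match the grid")

    @property
    def n_layers(self) -> int:
        return int(self.data.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        """(n_valid, p) matrix of layer values at valid cells."""
        return self.data[:, self.mask].T

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def select(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(
            names=list(names),
            data=self.data[idx],
            mask=self.mask.copy(),
            cellsize=self.cellsize,
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            units={n: self.units[n] for n in names if n in self.units},
        )

    # -- coordinate <-> cell ------------------------------------------------

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y); half-open cells."""
        rows, cols = self.shape
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yllcorner) / self.cellsize))
        row = rows - 1 - row_from_bottom
        if not (0 <= row < rows and 0 <= col < cols):
            raise ValueError(
                f"point ({x}, {y}) falls outside the raster extent "
                f"[{self.xllcorner}, {self.xllcorner + cols * self.cellsize}) x "
                f"[{self.yllcorner}, {self.yllcorner + rows * self.cellsize})"
            )
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        rows, _ = self.shape
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (rows - row - 0.5) * self.cellsize
        return x, y

    def values_at(self, cells: Sequence[tuple[int, int]]) -> np.ndarray:
        """(n_cells, p) matrix of layer values at the given (row, col) cells."""
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        return self.data[:, rows, cols].T


@dataclass
class PresenceSet:
    """Georeferenced presence records of one lineage, resolved to grid cells.

    cells: list of (row, col); weights: positive per-record weights (default
    1; a weight can encode several populations sharing a 1-km cell);
    coordinates: source map coordinates; metadata carries simulation ground
    truth (e.g. the true niche optimum) for recovery tests.
    """

    lineage: str
    cells: list[tuple[int, int]]
    weights: np.ndarray | None = None
    coordinates: list[tuple[float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.ones(len(self.cells))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.cells):
            raise ValueError("one weight per cell required")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return len(self.cells)

    def validate_against(self, stack: RasterStack) -> None:
        for r, c in self.cells:
            if not stack.mask[r, c]:
                raise ValueError(f"presence cell ({r}, {c}) is outside the valid mask")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    mask: np.ndarray | None = None,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = DEFAULT_NODATA,
) -> None:
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = nodata
    out[np.isnan(out)] = nodata
    rows, cols = out.shape
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {xllcorner!r}\nyllcorner {yllcorner!r}\n"
        f"cellsize {cellsize!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Returns (grid with NaN at nodata, validity mask, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: missing ncols/nrows header")
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = grid != nodata
    grid = np.where(mask, grid, np.nan)
    return grid, mask, header


def write_stack(stack: RasterStack, directory: str | Path) -> list[Path]:
    """One .asc file per layer, named after the layer."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, name in enumerate(stack.names):
        p = directory / f"{name}.asc"
        write_ascii_grid(
            p, stack.data[k], stack.mask, stack.cellsize,
            stack.xllcorner, stack.yllcorner,
        )
        paths.append(p)
    return paths


def read_stack(paths: Sequence[str | Path], names: Sequence[str] | None = None) -> RasterStack:
    """Load co-registered .asc layers; the joint mask is the AND of layer masks."""
    grids, masks = [], []
    ref_header: Mapping[str, float] | None = None
    for p in paths:
        grid, mask, header = read_ascii_grid(p)
        if ref_header is None:
            ref_header = header
        else:
            for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
                if not np.isclose(header.get(key, 0), ref_header.get(key, 0)):
                    raise ValueError(f"{p}: grid geometry mismatch on {key}")
        grids.append(grid)
        masks.append(mask)
    assert ref_header is not None
    joint = np.logical_and.reduce(masks)
    data = np.stack([np.where(joint, g, np.nan) for g in grids])
    if names is None:
        names = [Path(p).stem for p in paths]
    return RasterStack(
        names=list(names),
        data=data,
        mask=joint,
        cellsize=ref_header.get("cellsize", 1.0),
        xllcorner=ref_header.get("xllcorner", 0.0),
        yllcorner=ref_header.get("yllcorner", 0.0),
    )
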