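"""Rasterization of object records into the baseline biodiversity feature stack.

Tree lists become per-species grids of maximum height (Hmax), mean height
(Hmean) and total stem volume (Vol); downed-deadwood segments become a
species-agnostic volume grid (DDWVol) with each trunk's volume split across
cells in proportion to the trunk length falling inside each cell.
Stratifying the 13 variable grids by the four site-fertility classes yields
the 52-layer baseline stack used for prioritization.

Grid conventions: origin top-left, row-major, half-open cells
``[x0, x0+cs)`` — an object exactly on a shared edge belongs to the cell on
its right/below; objects on the far edge of the extent clamp into the last
cell.  Cells holding no objects get the value 0 (not NoData), so coarse
block means and sums are always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import SPECIES, SITE_CLASSES, SiteClassGrid

VARIABLES = ("Hmax", "Hmean", "Vol", "DDWVol")

#: Aggregation rule bound to each variable when coarsening the grid.
AGGREGATION_RULE = {"Hmax": "max", "Hmean": "mean", "Vol": "sum", "DDWVol": "sum"}


@dataclass(frozen=True)
class FeatureLayer:
    """One raster of a biodiversity variable, optionally site-stratified.

    ``species`` is ``"none"`` for DDWVol; ``site_class`` is ``None`` for the
    unstratified intermediate layers and 1..4 after stratification.
    """

    variable: str
    species: str
    site_class: int | None
    resolution: float
    values: np.ndarray  # (nrows, ncols) float64, finite, >= 0

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.species not in SPECIES + ("none",):
            raise ValueError(f"unknown species {self.species!r}")
        if self.site_class is not None and self.site_class not in SITE_CLASSES:
            raise ValueError(f"site_class must be 1..4 or None, got {self.site_class!r}")
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("layer values must be finite")
        if (v < 0).any():
            raise ValueError("layer values must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def name(self) -> str:
        base = self.variable if self.species == "none" else f"{self.variable}_{self.species}"
        return base if self.site_class is None else f"{base}_f{self.site_class}"

    @property
    def rule(self) -> str:
        return AGGREGATION_RULE[self.variable]


@dataclass(frozen=True)
class FeatureStack:
    """Ordered collection of feature layers at one resolution."""

    resolution: float
    layers: tuple[FeatureLayer, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        shapes = {lyr.values.shape for lyr in self.layers}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree on grid shape: {sorted(shapes)}")
        for lyr in self.layers:
            if lyr.resolution != self.resolution:
                raise ValueError(
                    f"layer {lyr.name} at {lyr.resolution} m in a {self.resolution} m stack"
                )

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].values.shape

    @property
    def n_cells(self) -> int:
        r, c = self.shape
        return r * c

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def manifest(self) -> list[dict]:
        return [
            {
                "index": i,
                "name": lyr.name,
                "variable": lyr.variable,
                "species": lyr.species,
                "site_class": lyr.site_class,
            }
            for i, lyr in enumerate(self.layers)
        ]

    def get(self, variable: str, species: str, site_class: int | None) -> FeatureLayer:
        for lyr in self.layers:
            if (lyr.variable, lyr.species, lyr.site_class) == (variable, species, site_class):
                return lyr
        raise KeyError(f"no layer ({variable}, {species}, {site_class})")

    def to_matrix(self) -> np.ndarray:
        """Cells-by-features value matrix (row-major cell order)."""
        return np.column_stack([lyr.values.ravel() for lyr in self.layers])


def _cell_indices(
    x: np.ndarray, y: np.ndarray, extent_x: float, extent_y: float, cell_size: float
) -> tuple[np.ndarray, np.ndarray]:
    bad = (x < 0) | (x > extent_x) | (y < 0) | (y > extent_y)
    if bad.any():
        offenders = np.flatnonzero(bad)[:10].tolist()
        raise ValueError(f"records outside extent at row indices {offenders}")
    ncols = int(round(extent_x / cell_size))
    nrows = int(round(extent_y / cell_size))
    col = np.minimum((x / cell_size).astype(int), ncols - 1)
    row = np.minimum((y / cell_size).astype(int), nrows - 1)
    return row, col


def rasterize_trees(
    trees: pd.DataFrame,
    extent_x: float,
    extent_y: float,
    cell_size: float = 16.0,
) -> list[FeatureLayer]:
    """Bin the tree list into 12 unstratified layers (Hmax, Hmean, Vol x species).

    Per cell and species: Hmax is the maximum height, Hmean the arithmetic
    mean height, Vol the summed stem volume; cells without trees of the
    species get 0.  Trees outside the extent raise an error listing offending
    row indices.
    """
    nrows = int(round(extent_y / cell_size))
    ncols = int(round(extent_x / cell_size))
    layers: list[FeatureLayer] = []
    x = trees["x"].to_numpy(dtype=float) if len(trees) else np.empty(0)
    y = trees["y"].to_numpy(dtype=float) if len(trees) else np.empty(0)
    row, col = _cell_indices(x, y, extent_x, extent_y, cell_size)
    flat = row * ncols + col
    for sp in SPECIES:
        sel = (trees["species"] == sp).to_numpy() if len(trees) else np.zeros(0, bool)
        idx = flat[sel]
        h = trees.loc[sel, "height_m"].to_numpy(dtype=float) if sel.any() else np.empty(0)
        v = trees.loc[sel, "vol_m3"].to_numpy(dtype=float) if sel.any() else np.empty(0)
        hmax = np.zeros(nrows * ncols)
        hsum = np.zeros(nrows * ncols)
        cnt = np.zeros(nrows * ncols)
        vol = np.zeros(nrows * ncols)
        np.maximum.at(hmax, idx, h)
        np.add.at(hsum, idx, h)
        np.add.at(cnt, idx, 1.0)
        np.add.at(vol, idx, v)
        hmean = np.divide(hsum, cnt, out=np.zeros_like(hsum), where=cnt > 0)
        for var, grid in (("Hmax", hmax), ("Hmean", hmean), ("Vol", vol)):
            layers.append(
                FeatureLayer(
                    variable=var,
                    species=sp,
                    site_class=None,
                    resolution=float(cell_size),
                    values=grid.reshape(nrows, ncols),
                )
            )
    return layers


def _split_segment_lengths(
    x1: float, y1: float, x2: float, y2: float, cell_size: float, nrows: int, ncols: int
) -> list[tuple[int, int, float]]:
    """Within-cell lengths of one segment: list of (row, col, length)."""
    length = float(np.hypot(x2 - x1, y2 - y1))
    if length == 0.0:
        col = min(int(x1 / cell_size), ncols - 1)
        row = min(int(y1 / cell_size), nrows - 1)
        return [(row, col, 0.0)]
    # breakpoints where the segment crosses grid lines, as parameters t in [0,1]
    ts = [0.0, 1.0]
    for lo, hi, d, o in ((x1, x2, x2 - x1, x1), (y1, y2, y2 - y1, y1)):
        if d == 0.0:
            continue
        kmin = int(np.ceil(min(lo, hi) / cell_size))
        kmax = int(np.floor(max(lo, hi) / cell_size))
        for k in range(kmin, kmax + 1):
            t = (k * cell_size - o) / d
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    parts: list[tuple[int, int, float]] = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        mx = x1 + tm * (x2 - x1)
        my = y1 + tm * (y2 - y1)
        col = min(int(mx / cell_size), ncols - 1)
        row = min(int(my / cell_size), nrows - 1)
        parts.append((row, col, (tb - ta) * length))
    return parts


def rasterize_ddw(
    ddw: pd.DataFrame,
    extent_x: float,
    extent_y: float,
    cell_size: float = 16.0,
) -> FeatureLayer:
    """Allocate downed-deadwood volume to grid cells.

    Each trunk's volume is split across the cells it crosses in proportion to
    the within-cell length, so the cell sums conserve the total record volume
    exactly.  A zero-length (degenerate) record contributes its whole volume
    to its containing cell.
    """
    nrows = int(round(extent_y / cell_size))
    ncols = int(round(extent_x / cell_size))
    grid = np.zeros((nrows, ncols))
    if len(ddw):
        ends = ddw[["x1", "y1", "x2", "y2"]].to_numpy(dtype=float)
        bad = (ends < -1e-9).any(axis=1) | (ends[:, [0, 2]] > extent_x + 1e-9).any(axis=1) | (
            ends[:, [1, 3]] > extent_y + 1e-9
        ).any(axis=1)
        if bad.any():
            offenders = np.flatnonzero(bad)[:10].tolist()
            raise ValueError(f"records outside extent at row indices {offenders}")
        vols = ddw["vol_m3"].to_numpy(dtype=float)
        for (x1, y1, x2, y2), vol in zip(ends, vols):
            parts = _split_segment_lengths(x1, y1, x2, y2, cell_size, nrows, ncols)
            total = sum(p[2] for p in parts)
            if total == 0.0:
                row, col, _ = parts[0]
                grid[row, col] += vol
            else:
                for row, col, ln in parts:
                    grid[row, col] += vol * ln / total
    return FeatureLayer(
        variable="DDWVol", species="none", site_class=None, resolution=float(cell_size), values=grid
    )


def stratify(layers: list[FeatureLayer], site_grid: SiteClassGrid) -> FeatureStack:
    """Split each unstratified layer into one layer per site-fertility class.

    The class-c layer equals the input where the site class is c and 0
    elsewhere, so for any (variable, species) the four stratified layers
    partition the unstratified one.  12 tree layers + 1 DDW layer yield the
    52-layer baseline stack.
    """
    out: list[FeatureLayer] = []
    for lyr in layers:
        if lyr.values.shape != site_grid.classes.shape:
            raise ValueError(
                f"layer {lyr.name} shape {lyr.values.shape} does not match "
                f"site grid {site_grid.classes.shape}"
            )
        if lyr.resolution != site_grid.cell_size:
            raise ValueError(
                f"layer {lyr.name} at {lyr.resolution} m vs site grid {site_grid.cell_size} m"
            )
        for cls in SITE_CLASSES:
            mask = site_grid.classes == cls
            out.append(
                replace(lyr, site_class=cls, values=np.where(mask, lyr.values, 0.0))
            )
    return FeatureStack(resolution=layers[0].resolution, layers=tuple(out))


def build_baseline_stack(
    trees: pd.DataFrame,
    ddw: pd.DataFrame,
    site_grid: SiteClassGrid,
) -> FeatureStack:
    """Rasterize trees and DDW at the site grid's resolution and stratify."""
    cs = site_grid.cell_size
    layers = rasterize_trees(trees, site_grid.extent_x, site_grid.extent_y, cs)
    layers.append(rasterize_ddw(ddw, site_grid.extent_x, site_grid.extent_y, cs))
    return stratify(layers, site_grid)
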