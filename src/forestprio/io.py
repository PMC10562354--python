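"""File formats: ESRI ASCII grids for rasters, CSV object tables, JSON manifests.

A feature stack is persisted as a directory holding one ``.asc`` grid per
layer plus a ``manifest.json`` mapping layer index to (variable, species,
site class) and recording the resolution.  Values are written with 17
significant digits so a write/read round trip reproduces float64 values
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureLayer, FeatureStack
from .landscape import DDW_COLUMNS, TREE_COLUMNS, SiteClassGrid

NODATA = -1.0


def write_ascii_grid(
    values: np.ndarray, path: str | Path, cell_size: float, nodata: float = NODATA
) -> None:
    """Write one grid as an ESRI ASCII raster (local Cartesian CRS, origin 0,0)."""
    values = np.asarray(values)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII raster; returns (values, cell_size, nodata)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.asarray(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid body {values.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return values, header["cellsize"], header.get("nodata_value", NODATA)


def write_stack(stack: FeatureStack, out_dir: str | Path) -> Path:
    """Persist a feature stack as per-layer ASCII grids plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"resolution": stack.resolution, "layers": []}
    for i, lyr in enumerate(stack):
        fname = f"{i:03d}_{lyr.name}.asc"
        write_ascii_grid(lyr.values, out / fname, stack.resolution)
        manifest["layers"].append(
            {
                "file": fname,
                "variable": lyr.variable,
                "species": lyr.species,
                "site_class": lyr.site_class,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_stack(in_dir: str | Path) -> FeatureStack:
    """Load a feature stack written by :func:`write_stack`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing stack manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    layers = []
    for entry in manifest["layers"]:
        path = in_dir / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest names missing layer file {path}")
        values, cell_size, _ = read_ascii_grid(path)
        if cell_size != manifest["resolution"]:
            raise ValueError(
                f"{path}: cell size {cell_size} disagrees with manifest "
                f"resolution {manifest['resolution']}"
            )
        layers.append(
            FeatureLayer(
                variable=entry["variable"],
                species=entry["species"],
                site_class=entry["site_class"],
                resolution=manifest["resolution"],
                values=values,
            )
        )
    return FeatureStack(resolution=manifest["resolution"], layers=tuple(layers))


def write_site_grid(grid: SiteClassGrid, path: str | Path) -> None:
    write_ascii_grid(grid.classes.astype(float), path, grid.cell_size)


def read_site_grid(path: str | Path) -> SiteClassGrid:
    values, cell_size, _ = read_ascii_grid(path)
    return SiteClassGrid(classes=values.astype(int), cell_size=cell_size)


def write_trees_csv(trees: pd.DataFrame, path: str | Path) -> None:
    trees.loc[:, list(TREE_COLUMNS)].to_csv(path, index=False)


def read_trees_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tree table missing column(s) {sorted(missing)}")
    return df


def write_ddw_csv(ddw: pd.DataFrame, path: str | Path) -> None:
    ddw.loc[:, list(DDW_COLUMNS)].to_csv(path, index=False)


def read_ddw_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DDW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DDW table missing column(s) {sorted(missing)}")
    return df
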