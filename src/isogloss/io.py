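"""Plain-text I/O: ESRI ASCII grids, CSV tables, GeoJSON contours, YAML config."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import PopulationRaster
from .dynamics import IsoglossContour

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_contours_geojson",
    "write_contours_csv",
    "write_xyz_csv",
    "read_xyz_csv",
]

NODATA = -9999.0


def write_ascii_grid(raster: PopulationRaster, path: str | Path) -> None:
    """ESRI ASCII grid; off-land cells are written as NODATA.

    The grid's first array index (x) maps to columns east, the second (y)
    to rows north, so the array is transposed and flipped into the
    row-major north-to-south layout of the format.
    """
    vals = np.where(raster.land_mask, raster.values, NODATA)
    rows = vals.T[::-1]  # north to south
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.shape[0]}\n")
        fh.write(f"nrows {raster.shape[1]}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in rows:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path, boundary_mode: str = "closed") -> PopulationRaster:
    header: dict[str, float] = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append([float(v) for v in parts])
    arr = np.array(data_lines)
    nodata = header.get("nodata_value", NODATA)
    vals = arr[::-1].T  # back to (x, y) with y north
    mask = vals != nodata
    vals = np.where(mask, vals, 0.0)
    return PopulationRaster(
        vals,
        cell_size=header.get("cellsize", 1.0),
        land_mask=mask,
        boundary_mode=boundary_mode,  # type: ignore[arg-type]
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_contours_geojson(
    contours: list[IsoglossContour], path: str | Path
) -> None:
    feats = []
    for k, c in enumerate(contours):
        feats.append(
            {
                "type": "Feature",
                "properties": {"id": k, "closed": c.closed, "length": c.length()},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in c.vertices],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_contours_csv(contours: list[IsoglossContour], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["contour", "vertex", "x", "y", "curvature", "nx", "ny", "closed"])
        for k, c in enumerate(contours):
            for i, (xy, kap, nrm) in enumerate(zip(c.vertices, c.curvature, c.normal)):
                w.writerow(
                    [k, i, f"{xy[0]:.6g}", f"{xy[1]:.6g}", f"{kap:.6g}",
                     f"{nrm[0]:.6g}", f"{nrm[1]:.6g}", int(c.closed)]
                )


def write_xyz_csv(raster: PopulationRaster, path: str | Path) -> None:
    X, Y = raster.coords()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "value"])
        for i, j in np.argwhere(raster.land_mask):
            w.writerow([X[i, j], Y[i, j], raster.values[i, j]])


def read_xyz_csv(path: str | Path, boundary_mode: str = "closed") -> PopulationRaster:
    """Small-fixture reader: x, y, value triplets on a complete regular grid."""
    xs, ys, vs = [], [], []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            xs.append(float(row["x"]))
            ys.append(float(row["y"]))
            vs.append(float(row["value"]))
    ux, uy = np.unique(xs), np.unique(ys)
    cell = float(np.diff(ux)[0]) if len(ux) > 1 else 1.0
    vals = np.zeros((len(ux), len(uy)))
    mask = np.zeros_like(vals, dtype=bool)
    for x, y, v in zip(xs, ys, vs):
        i = int(round((x - ux[0]) / cell))
        j = int(round((y - uy[0]) / cell))
        vals[i, j] = v
        mask[i, j] = True
    return PopulationRaster(
        vals, cell_size=cell, land_mask=mask,
        boundary_mode=boundary_mode,  # type: ignore[arg-type]
        origin=(float(ux[0]), float(uy[0])),
    )
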