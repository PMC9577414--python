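"""Equal-area hexagonal tessellation carrying environmental layers.

The study area is discretised into pointy-top hexagons of exactly equal area
(default ~1.18 km^2). Each cell carries the environmental layers the dispersal
pipeline consumes: elevation, NDVI, propagule-source presence, establishment
suitability, landcover class and management zone. Cells are addressed by an
integer ``cell_id``; axial coordinates (q, r) are kept internally for O(1)
point-in-cell lookup via cube rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

SQRT3 = np.sqrt(3.0)

#: layers every grid exposes; NaN / placeholder until populated
LAYER_COLUMNS = ["elevation", "ndvi", "guava_present", "suitable", "landcover", "zone"]


def hex_size_for_area(area_km2: float) -> float:
    """Circumradius (m) of a regular hexagon with the given area (km^2)."""
    if area_km2 <= 0:
        raise ValueError("hex area must be positive")
    return float(np.sqrt(2.0 * area_km2 * 1e6 / (3.0 * SQRT3)))


def _axial_to_xy(q, r, size):
    x = size * SQRT3 * (np.asarray(q) + np.asarray(r) / 2.0)
    y = size * 1.5 * np.asarray(r)
    return x, y


def _xy_to_axial_frac(x, y, size):
    q = (SQRT3 / 3.0 * np.asarray(x) - np.asarray(y) / 3.0) / size
    r = (2.0 / 3.0 * np.asarray(y)) / size
    return q, r


def _cube_round(qf, rf):
    """Round fractional axial coordinates to the containing hexagon."""
    xf, zf = np.asarray(qf, dtype=float), np.asarray(rf, dtype=float)
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


@dataclass
class HexGrid:
    """Hexagonal grid over a planar (metric) domain.

    Parameters
    ----------
    cells : DataFrame indexed by ``cell_id`` with columns ``q, r, x, y`` plus
        the environmental ``LAYER_COLUMNS``.
    size_m : hexagon circumradius in metres (all cells identical).
    """

    cells: pd.DataFrame
    size_m: float
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.cells.index.duplicated().any():
            raise ValueError("cell_ids must be unique")
        self._lookup = {
            (int(q), int(r)): int(cid)
            for cid, q, r in zip(self.cells.index, self.cells["q"], self.cells["r"])
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def covering_box(cls, xmin, ymin, xmax, ymax, area_km2: float = 1.18) -> "HexGrid":
        """Grid of equal-area hexagons whose centres cover a bounding box."""
        size = hex_size_for_area(area_km2)
        rmin = int(np.floor(ymin / (1.5 * size))) - 1
        rmax = int(np.ceil(ymax / (1.5 * size))) + 1
        rows = []
        for r in range(rmin, rmax + 1):
            qmin = int(np.floor(xmin / (SQRT3 * size) - r / 2.0)) - 1
            qmax = int(np.ceil(xmax / (SQRT3 * size) - r / 2.0)) + 1
            for q in range(qmin, qmax + 1):
                rows.append((q, r))
        q = np.array([t[0] for t in rows])
        r = np.array([t[1] for t in rows])
        x, y = _axial_to_xy(q, r, size)
        keep = (x >= xmin - size) & (x <= xmax + size) & (y >= ymin - size) & (y <= ymax + size)
        df = pd.DataFrame({"q": q[keep], "r": r[keep], "x": x[keep], "y": y[keep]})
        df.index.name = "cell_id"
        for col in LAYER_COLUMNS:
            df[col] = np.nan
        df["guava_present"] = False
        df["suitable"] = True
        df["landcover"] = ""
        df["zone"] = ""
        return cls(df, size)

    # -- geometry ----------------------------------------------------------

    @property
    def area_km2(self) -> float:
        return 1.5 * SQRT3 * self.size_m**2 / 1e6

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy()

    def polygon(self, cell_id: int) -> Polygon:
        cx, cy = self.cells.loc[cell_id, ["x", "y"]]
        ang = np.radians(60.0 * np.arange(6) + 30.0)  # pointy-top
        return Polygon(zip(cx + self.size_m * np.cos(ang), cy + self.size_m * np.sin(ang)))

    def locate(self, x, y) -> np.ndarray:
        """cell_id containing each planar point; -1 where outside the grid."""
        qf, rf = _xy_to_axial_frac(x, y, self.size_m)
        q, r = _cube_round(qf, rf)
        flat_q, flat_r = np.atleast_1d(q), np.atleast_1d(r)
        out = np.fromiter(
            (self._lookup.get((int(a), int(b)), -1) for a, b in zip(flat_q, flat_r)),
            dtype=int, count=len(flat_q),
        )
        return out if np.ndim(x) else out[0]

    # -- serialisation -----------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.cells.copy()
        df["hex_size_m"] = self.size_m
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "HexGrid":
        df = pd.read_csv(path, index_col="cell_id")
        size = float(df.pop("hex_size_m").iloc[0])
        return cls(df, size)

    def to_geojson(self, path, value_columns=None, projection=None) -> None:
        """Write cells as GeoJSON polygons (planar coords, or lon/lat if a
        projection is supplied); layer values go into feature properties."""
        value_columns = list(value_columns or LAYER_COLUMNS)
        feats = []
        for cid in self.cells.index:
            poly = self.polygon(cid)
            if projection is not None:
                xs, ys = poly.exterior.xy
                lon, lat = projection.inverse(np.asarray(xs), np.asarray(ys))
                poly = Polygon(zip(lon, lat))
            props = {"cell_id": int(cid)}
            for col in value_columns:
                v = self.cells.loc[cid, col]
                props[col] = v.item() if hasattr(v, "item") else v
            feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
        obj = {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {"crs": "local metric" if projection is None else "EPSG:4326",
                           "units": "m" if projection is None else "degrees"},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)
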