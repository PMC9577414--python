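"""Track handling, net squared displacement, daily thinning and seasonal ranges.

Seasonal ranges follow the standard telemetry workflow: per-individual kernel
utilization distributions (UDs), a population-level convex hull around the
seasonal UDs, and conversion to presence/absence on the hexagonal grid by
centroid-in-hull membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

from .crs import LocalProjection
from .grid import HexGrid

TRACK_COLUMN_ALIASES = {
    "individual-local-identifier": "individual_id",
    "location-long": "lon",
    "location-lat": "lat",
    "longitude": "lon",
    "latitude": "lat",
}


@dataclass
class Track:
    """One individual's GPS track: ordered (timestamp, lon, lat) fixes.

    Extra columns (e.g. a movement-phase label from a segmentation step) are
    preserved in ``fixes`` and carried through thinning.
    """

    individual_id: str
    fixes: pd.DataFrame  # columns: timestamp (datetime64), lon, lat [, ...]

    def __post_init__(self):
        f = self.fixes
        if not f["timestamp"].is_monotonic_increasing or f["timestamp"].duplicated().any():
            raise ValueError(f"track {self.individual_id}: timestamps must be strictly increasing")
        if not np.isfinite(f[["lon", "lat"]].to_numpy()).all():
            raise ValueError(f"track {self.individual_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.fixes)

    def xy(self, projection: LocalProjection) -> np.ndarray:
        """Planar (n, 2) coordinates in metres under the given projection."""
        x, y = projection.forward(self.fixes["lon"].to_numpy(), self.fixes["lat"].to_numpy())
        return np.column_stack([x, y])

    def local_projection(self) -> LocalProjection:
        """Projection centred on the track's mean position."""
        return LocalProjection(float(self.fixes["lon"].mean()), float(self.fixes["lat"].mean()))


def read_tracks_csv(path) -> list[Track]:
    """Read Movebank-style track CSV into per-individual :class:`Track`s."""
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in TRACK_COLUMN_ALIASES.items() if k in df.columns})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        out.append(Track(str(ind), sub))
    return out


def write_tracks_csv(tracks: list[Track], path) -> None:
    pd.concat([t.fixes.assign(individual_id=t.individual_id) for t in tracks],
              ignore_index=True).to_csv(path, index=False)


def compute_nsd(track: Track, projection: LocalProjection | None = None) -> pd.DataFrame:
    """Net squared displacement (m^2) of every fix relative to the first.

    Sustained NSD increase is the classical signature of migration onset in
    telemetry data; the first value is 0 by construction.
    """
    if len(track) < 2:
        raise ValueError("NSD needs at least 2 fixes")
    proj = projection or LocalProjection(float(track.fixes["lon"].iloc[0]),
                                         float(track.fixes["lat"].iloc[0]))
    xy = track.xy(proj)
    d2 = ((xy - xy[0]) ** 2).sum(axis=1)
    return pd.DataFrame({"timestamp": track.fixes["timestamp"].to_numpy(), "nsd_m2": d2})


def flag_migration_windows(nsd: pd.DataFrame, rise_m2: float, min_days: int = 3) -> list[tuple]:
    """Candidate migration windows: maximal runs of days over which NSD rises
    by more than ``rise_m2`` from the run's start. A reproducible stand-in for
    eyeballing NSD plots; callers segment tracks with it or supply their own
    segmentation.
    """
    ts = pd.to_datetime(nsd["timestamp"])
    daily = nsd.groupby(ts.dt.normalize())["nsd_m2"].first()
    vals, days = daily.to_numpy(), daily.index
    windows, start = [], None
    for i in range(1, len(vals)):
        rising = vals[i] > vals[i - 1]
        if rising and start is None:
            start = i - 1
        if start is not None and (not rising or i == len(vals) - 1):
            end = i if rising else i - 1
            if end - start + 1 >= min_days and vals[end] - vals[start] > rise_m2:
                windows.append((days[start], days[end]))
            start = None
    return windows


def thin_daily(track: Track) -> Track:
    """Keep the first fix of each calendar day (idempotent)."""
    f = track.fixes
    days = pd.to_datetime(f["timestamp"]).dt.normalize()
    keep = ~days.duplicated()
    return Track(track.individual_id, f[keep].reset_index(drop=True))


def estimate_ud(track: Track, isopleth: float = 0.95,
                projection: LocalProjection | None = None,
                grid_res: int = 128):
    """Kernel UD isopleth polygon for one track.

    A Gaussian KDE with the reference (Silverman) bandwidth is evaluated on a
    raster over the padded bounding box of the fixes; the isopleth region is
    the union of raster pixels of highest density holding >= ``isopleth`` of
    the total mass. Tracks with fewer than 30 fixes fall back (with a warning)
    to the convex hull of the fixes.
    """
    if not 0 < isopleth <= 1:
        raise ValueError("isopleth must be in (0, 1]")
    proj = projection or track.local_projection()
    xy = track.xy(proj)
    if np.allclose(xy, xy[0]):
        raise ValueError("degenerate kernel: all fixes identical")
    if len(xy) < 30:
        warnings.warn(f"track {track.individual_id}: <30 fixes, using convex hull "
                      "instead of a kernel UD", stacklevel=2)
        return MultiPoint(xy).convex_hull.buffer(1.0)

    kde = gaussian_kde(xy.T)  # Silverman-type reference bandwidth
    bw = np.sqrt(np.diag(kde.covariance))
    pad = 3.0 * bw
    x0, y0 = xy.min(axis=0) - pad
    x1, y1 = xy.max(axis=0) + pad
    gx = np.linspace(x0, x1, grid_res)
    gy = np.linspace(y0, y1, grid_res)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)

    order = np.argsort(dens.ravel())[::-1]
    csum = np.cumsum(dens.ravel()[order])
    n_keep = int(np.searchsorted(csum, isopleth * csum[-1])) + 1
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:n_keep]] = True
    mask = mask.reshape(dens.shape)

    # merge selected pixels into per-row strips before the union (fast path)
    dx = (gx[1] - gx[0]) / 2.0
    dy = (gy[1] - gy[0]) / 2.0
    strips = []
    for i in range(mask.shape[0]):
        row = mask[i]
        if not row.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[False], row, [False]])))
        for j0, j1 in edges.reshape(-1, 2):
            strips.append(box(gx[j0] - dx, gy[i] - dy, gx[j1 - 1] + dx, gy[i] + dy))
    return unary_union(strips)


@dataclass
class SeasonalRange:
    """Population-level seasonal range on the hex grid."""

    season: str  # "highland" | "lowland"
    member_cells: set = field(default_factory=set)
    source_polygon: Polygon | None = None

    def __post_init__(self):
        if not self.member_cells:
            raise ValueError(f"{self.season} range has no member cells")


def seasonal_range(uds: list, grid: HexGrid, season: str) -> SeasonalRange:
    """Convex hull around the union of UDs, converted to grid presences.

    Membership is centroid-in-hull: a cell belongs to the seasonal range iff
    its centroid falls inside the population hull.
    """
    if not uds:
        raise ValueError("need at least one UD polygon")
    hull = unary_union(uds).convex_hull
    xy = grid.centroids()
    inside = shapely.contains_xy(hull, xy[:, 0], xy[:, 1])
    members = set(grid.cells.index[inside].tolist())
    if not members:
        raise ValueError("population hull covers no cell centroid")
    return SeasonalRange(season=season, member_cells=members, source_polygon=hull)
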