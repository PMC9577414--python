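"""Self-contained synthetic island study system.

Generates every input the dispersal pipeline consumes — hex grid with
elevation/NDVI/source-plant/suitability/landcover/zone layers, phase-labelled
migration tracks, and an "observed" dung-pile dataset — with the statistical
structure the model assumes: a conical island with an elevational gradient,
NDVI decreasing with elevation, a highland seasonal range around the summit,
a lowland range confined to a coastal sector, source plants covering a
configurable fraction of the highland, and downslope migration tracks with
serially correlated headings.

The generator is deliberately schematic: it emulates structure (gradients,
bands, zoning, track geometry), not any real island's geography or
seasonality. Track step lengths are gamma distributed and heading deviations
follow a wrapped-normal AR(1) process; the parameters are recorded in the
bundle so kernel-fitting recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crs import LocalProjection
from .grid import HexGrid
from .movement import Track

SECTOR_CENTER_DEG = -90.0   # population's coastal sector points due south
SECTOR_HALF_WIDTH_DEG = 30.0
LANDCOVER_BANDS = [          # (upper elevation m, class) — schematic zoning
    (75.0, "shrubland"),
    (200.0, "grassland"),
    (300.0, "evergreen_forest"),
    (420.0, "invasive_thicket"),
    (np.inf, "agricultural_mosaic"),
]


@dataclass(frozen=True)
class IslandConfig:
    extent_km: float = 26.0
    hex_area_km2: float = 1.18
    elevation_peak_m: float = 480.0
    highland_band_m: tuple = (350.0, 480.0)
    lowland_band_m: tuple = (20.0, 140.0)
    guava_highland_fraction: float = 0.21
    n_tracks: int = 17
    residency_days: int = 40
    step_shape: float = 5.0       # gamma shape of migration daily steps
    step_scale_m: float = 90.0    # gamma scale -> mean daily step 450 m
    heading_ar: float = 0.5       # AR(1) coefficient of heading deviation
    heading_sd: float = 0.45      # wrapped-normal innovation sd (rad)
    rng_seed: int = 0
    include_dung_piles: bool = True

    def __post_init__(self):
        if not 0.0 <= self.guava_highland_fraction <= 1.0:
            raise ValueError("guava_highland_fraction must be in [0, 1]")
        if self.hex_area_km2 <= 0:
            raise ValueError("hex_area_km2 must be positive")
        lo, hi = self.lowland_band_m
        hlo, hhi = self.highland_band_m
        if not (lo < hi <= hlo < hhi):
            raise ValueError("elevation bands must be ordered and non-overlapping")

    @property
    def island_radius_m(self) -> float:
        return 0.95 * self.extent_km * 500.0  # 0.95 x half-extent


@dataclass
class SyntheticBundle:
    grid: HexGrid
    tracks: list
    dung_piles: pd.DataFrame
    highland_cells: set
    lowland_cells: set
    config: IslandConfig
    projection: LocalProjection
    track_params: dict = field(default_factory=dict)

    def migration_tracks(self) -> list[Track]:
        """Daily migration-phase segments (the pre-segmented input the
        trajectory simulator is calibrated from)."""
        out = []
        for t in self.tracks:
            seg = t.fixes[t.fixes["phase"] == "migration"].reset_index(drop=True)
            out.append(Track(t.individual_id, seg))
        return out

    def residency_tracks(self, season: str) -> list[Track]:
        phase = f"{season}_residency"
        out = []
        for t in self.tracks:
            seg = t.fixes[t.fixes["phase"] == phase].reset_index(drop=True)
            out.append(Track(t.individual_id, seg))
        return out


#: hypsometric profile control points (fraction of island radius, fraction of
#: peak elevation): a steep summit cone holding the highland seasonal range,
#: a gentle mid/lower apron and a flat coastal fringe — volcanic-island
#: hypsometry under which migrants cross the highland in a few days and then
#: spend most of the journey (and the retention tail) on the low slopes
PROFILE_R = np.array([0.0, 0.22, 0.75, 0.97, 1.0])
PROFILE_Z = np.array([1.0, 0.729, 0.1875, 0.0, 0.0])


def _elevation_of_radius(cfg: IslandConfig, r) -> np.ndarray:
    return cfg.elevation_peak_m * np.interp(
        np.asarray(r, dtype=float) / cfg.island_radius_m, PROFILE_R, PROFILE_Z)


def _radius_of_elevation(cfg: IslandConfig, elev: float) -> float:
    """Inverse hypsometric profile (the profile is monotone outside the flat
    coastal tail, so take the innermost radius attaining the elevation)."""
    z = elev / cfg.elevation_peak_m
    return cfg.island_radius_m * float(np.interp(-z, -PROFILE_Z[:-1], PROFILE_R[:-1]))


def _make_grid(cfg: IslandConfig, rng: np.random.Generator) -> HexGrid:
    half = cfg.extent_km * 500.0
    grid = HexGrid.covering_box(-half, -half, half, half, cfg.hex_area_km2)
    xy = grid.centroids()
    r = np.hypot(xy[:, 0], xy[:, 1])
    elev = _elevation_of_radius(cfg, r)
    elev = np.clip(elev + rng.normal(0.0, 3.0, len(elev)), 0.0, cfg.elevation_peak_m)
    ndvi = 0.15 + 0.6 * (1.0 - elev / cfg.elevation_peak_m)
    ndvi = np.clip(ndvi + rng.normal(0.0, 0.04, len(ndvi)), 0.05, 1.0)
    cells = grid.cells
    cells["elevation"] = elev
    cells["ndvi"] = ndvi
    lc = np.empty(len(elev), dtype=object)
    prev = -np.inf
    for upper, name in LANDCOVER_BANDS:
        lc[(elev > prev) & (elev <= upper)] = name
        prev = upper
    lc[elev == 0.0] = "shrubland"
    cells["landcover"] = lc
    cells["zone"] = np.where(elev >= cfg.highland_band_m[0], "agricultural", "park")
    # establishment suitable below the summit zone, with scattered unsuitable cells
    cells["suitable"] = (elev <= 0.75 * cfg.elevation_peak_m) & (rng.random(len(elev)) > 0.1)
    return grid


def _in_sector(x, y):
    az = np.degrees(np.arctan2(y, x))
    return np.abs(((az - SECTOR_CENTER_DEG) + 180.0) % 360.0 - 180.0) <= SECTOR_HALF_WIDTH_DEG


def _band_cells(grid: HexGrid, lo: float, hi: float, sector: bool) -> set:
    elev = grid.cells["elevation"].to_numpy()
    sel = (elev >= lo) & (elev <= hi)
    if sector:
        xy = grid.centroids()
        sel &= _in_sector(xy[:, 0], xy[:, 1])
    return set(grid.cells.index[sel].tolist())


def _wander(center: np.ndarray, n: int, sd: float, rng) -> np.ndarray:
    """Residency wander: mean-reverting jitter around a range centre; the
    first position is the centre itself (keeps track endpoints in-band)."""
    pos = np.zeros((n, 2))
    pos[0] = center
    for i in range(1, n):
        pos[i] = pos[i - 1] + 0.5 * (center - pos[i - 1]) + rng.normal(0, sd * 0.6, 2)
    return pos


def _migrate(start: np.ndarray, dest: np.ndarray, cfg: IslandConfig, rng) -> np.ndarray:
    """Downslope-biased correlated random walk from start to near dest."""
    pos = [start.copy()]
    dev = 0.0
    cur = start.copy()
    mean_step = cfg.step_shape * cfg.step_scale_m
    for _ in range(200):
        gap = dest - cur
        dist = float(np.hypot(*gap))
        if dist < 1.2 * mean_step:
            break
        bearing = np.arctan2(gap[1], gap[0])
        dev = cfg.heading_ar * dev + rng.normal(0.0, cfg.heading_sd)
        heading = bearing + dev
        step = rng.gamma(cfg.step_shape, cfg.step_scale_m)
        cur = cur + step * np.array([np.cos(heading), np.sin(heading)])
        pos.append(cur.copy())
    pos.append(dest.copy())
    return np.asarray(pos)


def _make_tracks(cfg: IslandConfig, grid: HexGrid, rng,
                 proj: LocalProjection) -> list[Track]:
    r_high = _radius_of_elevation(cfg, cfg.highland_band_m[0])
    r_low_in = _radius_of_elevation(cfg, cfg.lowland_band_m[1])
    r_low_out = _radius_of_elevation(cfg, cfg.lowland_band_m[0])
    tracks = []
    t0 = pd.Timestamp("2015-06-01 08:00:00")
    n = cfg.n_tracks
    for i in range(n):
        # highland residency centres: angles stratified around the summit so
        # the population of per-individual UDs spans the whole highland disk
        rc = r_high * rng.uniform(0.55, 0.8)
        ac = 2.0 * np.pi * (i + rng.uniform(0.2, 0.8)) / n
        c_high = rc * np.array([np.cos(ac), np.sin(ac)])
        high = _wander(c_high, cfg.residency_days, 350.0, rng)
        # destinations stratified across the coastal sector (angle slots,
        # alternating inner/outer radii) so the lowland hull spans the band;
        # resample until the migration leg is long enough to calibrate a
        # movement kernel (>= 12 daily steps)
        ad = np.radians(SECTOR_CENTER_DEG - SECTOR_HALF_WIDTH_DEG
                        + 2.0 * SECTOR_HALF_WIDTH_DEG * (i + rng.uniform(0.1, 0.9)) / n)
        for attempt in range(100):
            if attempt < 30:
                v = 0.8 * (i % 2) + rng.uniform(0.05, 0.15)
            else:  # widen the radius slot if the leg keeps coming out short
                v = rng.uniform(0.4, 0.95)
            rd = (r_low_in + 500.0) + v * (r_low_out - r_low_in - 1000.0)
            dest = rd * np.array([np.cos(ad), np.sin(ad)])
            mig = _migrate(high[-1], dest, cfg, rng)
            if len(mig) - 1 >= 12:
                break
        low = _wander(dest, cfg.residency_days, 350.0, rng)
        low[-1] = dest  # guarantee the track ends inside the lowland band

        xy = np.vstack([high, mig[1:], low[1:]])
        phase = (["highland_residency"] * len(high)
                 + ["migration"] * (len(mig) - 1)
                 + ["lowland_residency"] * (len(low) - 1))
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        fixes = pd.DataFrame({
            "timestamp": t0 + pd.to_timedelta(np.arange(len(xy)), unit="D"),
            "lon": lon, "lat": lat, "phase": phase,
        })
        tracks.append(Track(f"torto_{i:02d}", fixes))
    return tracks


def _make_dung_piles(cfg: IslandConfig, grid: HexGrid, tracks: list[Track],
                     proj: LocalProjection, rng) -> pd.DataFrame:
    """'Observed' dung piles: one small dispersal simulation, subsampled.

    Running the simulator itself (at a seed derived from the island seed) and
    subsampling its excretion events yields observed-style validation data
    with realistic spatial structure; piles without the source plant are
    placed at random visited stops.
    """
    from .connectivity import assign_individuals, energy_from_ndvi, solve_transport, transport_cost
    from .ertg import fit_kernel_from_xy, run_population
    from .gut import RetentionModel, SeedLoadModel, events_to_frame, simulate_dispersal
    from .movement import SeasonalRange

    highland = SeasonalRange("highland", _band_cells(grid, *cfg.highland_band_m, False))
    low = _band_cells(grid, *cfg.lowland_band_m, True)
    lowland = SeasonalRange("lowland", low)
    n_ind = 60
    H = energy_from_ndvi(grid, highland, n_ind)
    L = energy_from_ndvi(grid, lowland, n_ind)
    flow = solve_transport(H, L, transport_cost(grid, H, L))
    assigns = assign_individuals(flow, n_ind)
    kernels = []
    for t in tracks:
        seg = t.fixes[t.fixes["phase"] == "migration"]
        x, y = proj.forward(seg["lon"].to_numpy(), seg["lat"].to_numpy())
        kernels.append(fit_kernel_from_xy(t.individual_id, np.column_stack([x, y])))
    trajs = run_population(assigns, kernels, grid, rng)
    retention, loadm = RetentionModel(), SeedLoadModel()
    ev = []
    for tr in trajs:
        ev.extend(simulate_dispersal(tr, grid, retention, loadm, rng,
                                     feed_probability_init=cfg.guava_highland_fraction))
    events = events_to_frame(ev)
    n_guava = min(len(events), 120)
    guava_piles = events.sample(n=n_guava, random_state=int(rng.integers(2**31)))
    rows = []
    for _, e in guava_piles.iterrows():
        rows.append((e.x, e.y, e.elevation, True))
    # piles without the source plant, at random stops along trajectories
    for _ in range(max(20, n_guava)):
        tr = trajs[rng.integers(len(trajs))]
        p = tr.positions[rng.integers(len(tr.positions))]
        cid = grid.locate(p[0], p[1])
        if cid >= 0:
            rows.append((p[0], p[1], float(grid.cells.loc[cid, "elevation"]), False))
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    cid = grid.locate(x, y)
    lon, lat = proj.inverse(x, y)
    return pd.DataFrame({
        "x": x, "y": y, "lon": lon, "lat": lat,
        "elevation": [r[2] for r in rows],
        "contains_guava": [r[3] for r in rows],
        "landcover": grid.cells["landcover"].reindex(cid).to_numpy(),
        "zone": grid.cells["zone"].reindex(cid).to_numpy(),
        "source": "observed",
    })


def generate_island(config: IslandConfig | None = None) -> SyntheticBundle:
    """Generate the full synthetic study system (deterministic per seed)."""
    cfg = config or IslandConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    proj = LocalProjection(0.0, 0.0)
    grid = _make_grid(cfg, rng)

    highland_cells = _band_cells(grid, *cfg.highland_band_m, sector=False)
    lowland_cells = _band_cells(grid, *cfg.lowland_band_m, sector=True)
    if not highland_cells or not lowland_cells:
        raise ValueError("degenerate domain: a seasonal band contains no cells")

    # source plant on an exact fraction of highland cells (sampled without
    # replacement so the realised coverage matches the target)
    hl = np.array(sorted(highland_cells))
    n_src = int(round(cfg.guava_highland_fraction * len(hl)))
    src = rng.choice(hl, size=n_src, replace=False) if n_src else np.array([], dtype=int)
    grid.cells["guava_present"] = False
    grid.cells.loc[src, "guava_present"] = True

    tracks = _make_tracks(cfg, grid, rng, proj)
    if cfg.include_dung_piles:
        dung = _make_dung_piles(cfg, grid, tracks, proj, rng)
    else:
        dung = pd.DataFrame(columns=["x", "y", "lon", "lat", "elevation",
                                     "contains_guava", "landcover", "zone", "source"])
    params = {"step_shape": cfg.step_shape, "step_scale_m": cfg.step_scale_m,
              "heading_ar": cfg.heading_ar, "heading_sd": cfg.heading_sd}
    return SyntheticBundle(grid, tracks, dung, highland_cells, lowland_cells,
                           cfg, proj, params)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as plain-text artifacts (CSV layers/tracks, GeoJSON)."""
    import json
    from pathlib import Path

    from shapely.ops import unary_union

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.grid.to_csv(out / "grid_cells.csv")
    from .movement import write_tracks_csv
    write_tracks_csv(bundle.tracks, out / "tracks.csv")
    bundle.dung_piles.to_csv(out / "dung_piles.csv", index=False)
    feats = []
    for zone in ("park", "agricultural"):
        ids = bundle.grid.cells.index[bundle.grid.cells["zone"] == zone]
        geom = unary_union([bundle.grid.polygon(i) for i in ids])
        from shapely.geometry import mapping
        feats.append({"type": "Feature", "geometry": mapping(geom),
                      "properties": {"zone": zone}})
    with open(out / "zones.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats,
                   "properties": {"crs": "local metric", "units": "m"}}, fh)
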