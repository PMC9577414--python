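"""End-to-end pipeline orchestration: ranges -> connectivity -> trajectories
-> dispersal -> fate -> validation, with deterministic per-stage seeding and a
manifest describing every artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .connectivity import assign_individuals, energy_from_ndvi, solve_transport, transport_cost
from .ertg import fit_kernel_from_xy, run_population
from .fate import apply_fate_mask, ks_compare, summarize_deposition
from .grid import HexGrid
from .gut import RetentionModel, SeedLoadModel, accumulate_seed_rain, events_to_frame, simulate_dispersal
from .movement import estimate_ud, read_tracks_csv, seasonal_range, thin_daily
from .synthetic import IslandConfig, generate_island

STAGES = ("ranges", "connectivity", "trajectories", "dispersal", "fate", "validate")
log = logging.getLogger("migraseed.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; defaults match the full-scale study settings
    (1000 migrants, 25 stochastic repeats, one stop per day, 95% UDs)."""

    outdir: str = "runs/run"
    synthetic: bool = True
    grid_csv: str | None = None
    tracks_csv: str | None = None
    dung_csv: str | None = None
    population_size: int = 1000
    repeats: int = 25
    stops_per_day: int = 1
    settle_days: int | None = None
    isopleth: float = 0.95
    rng_seed: int = 0
    island: dict = field(default_factory=dict)  # IslandConfig overrides

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _substreams(master_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: PipelineConfig) -> Path:
    manifest = {
        "package": "migraseed", "version": __version__,
        "seed": config.rng_seed,
        "config": json.loads(config.to_json()),
        "crs": "local metric (m)",
        "artifacts": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def run_pipeline(config: PipelineConfig, until: str = "validate") -> Path:
    """Execute stages up to ``until``; returns the run directory. Any stage
    failure aborts with a :class:`StageError` naming the stage."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    # fixed number of substreams so stage results are stable as stages evolve
    _, _, rng_traj, rng_disp, _ = _substreams(config.rng_seed, 5)

    # ---- inputs ---------------------------------------------------------
    if config.synthetic:
        bundle = generate_island(IslandConfig(rng_seed=config.rng_seed, **config.island))
        grid, projection = bundle.grid, bundle.projection
        tracks, dung = bundle.tracks, bundle.dung_piles
    else:
        try:
            grid = HexGrid.from_csv(config.grid_csv)
            tracks = read_tracks_csv(config.tracks_csv)
            dung = pd.read_csv(config.dung_csv) if config.dung_csv else pd.DataFrame()
        except Exception as e:  # noqa: BLE001 - surfaced with stage context
            raise StageError("ranges", e) from e
        from .crs import LocalProjection
        projection = LocalProjection(float(np.mean([t.fixes["lon"].mean() for t in tracks])),
                                     float(np.mean([t.fixes["lat"].mean() for t in tracks])))

    # ---- ranges ---------------------------------------------------------
    try:
        uds = {"highland": [], "lowland": []}
        for t in tracks:
            t = thin_daily(t)
            has_phase = "phase" in t.fixes.columns
            for season in uds:
                if has_phase:
                    seg = t.fixes[t.fixes["phase"] == f"{season}_residency"]
                    if len(seg) < 2:
                        continue
                    sub = type(t)(t.individual_id, seg.reset_index(drop=True))
                else:
                    sub = t
                uds[season].append(estimate_ud(sub, config.isopleth, projection))
        ranges = {s: seasonal_range(uds[s], grid, s) for s in uds}
        for s, r in ranges.items():
            pd.Series(sorted(r.member_cells), name="cell_id").to_csv(
                out / f"range_{s}.csv", index=False)
    except StageError:
        raise
    except Exception as e:
        raise StageError("ranges", e) from e
    if until == "ranges":
        return _write_manifest(out, config)

    # ---- connectivity ---------------------------------------------------
    try:
        if grid.cells.loc[sorted(ranges["highland"].member_cells), "ndvi"].isna().any():
            raise ValueError("NDVI layer missing on highland range cells")
        H = energy_from_ndvi(grid, ranges["highland"], config.population_size)
        L = energy_from_ndvi(grid, ranges["lowland"], config.population_size)
        flow = solve_transport(H, L, transport_cost(grid, H, L))
        assigns = assign_individuals(flow, config.population_size)
        fdf = flow.to_frame()
        counts = pd.Series([(a.origin_cell, a.dest_cell) for a in assigns]).value_counts()
        fdf["count"] = [counts.get((o, d), 0) for o, d in zip(fdf["origin_cell"], fdf["dest_cell"])]
        fdf.to_csv(out / "flows.csv", index=False)
    except StageError:
        raise
    except Exception as e:
        raise StageError("connectivity", e) from e
    if until == "connectivity":
        return _write_manifest(out, config)

    # ---- trajectories + dispersal (stochastic repeats) ------------------
    try:
        kernels = []
        for t in tracks:
            t = thin_daily(t)
            f = t.fixes
            if "phase" in f.columns:
                f = f[f["phase"] == "migration"]
            x, y = projection.forward(f["lon"].to_numpy(), f["lat"].to_numpy())
            try:
                kernels.append(fit_kernel_from_xy(t.individual_id, np.column_stack([x, y])))
            except ValueError:
                log.warning("track %s: migration segment too short for a kernel, skipped",
                            t.individual_id)
        if not kernels:
            raise ValueError("no track long enough to calibrate a movement kernel")
    except Exception as e:
        raise StageError("trajectories", e) from e

    retention, loadm = RetentionModel(), SeedLoadModel()
    guava_frac = float(grid.cells.loc[sorted(ranges["highland"].member_cells),
                                      "guava_present"].mean())
    n_reps = 1 if until == "trajectories" else config.repeats
    event_frames, traj_rows = [], []
    for rep in range(n_reps):
        try:
            trajs = run_population(assigns, kernels, grid, rng_traj)
        except Exception as e:
            raise StageError("trajectories", e) from e
        if until == "trajectories":
            for tr in trajs:
                for k, (x, y) in enumerate(tr.positions):
                    traj_rows.append((tr.individual_id, k, x, y))
            break
        try:
            ev = []
            for tr in trajs:
                ev.extend(simulate_dispersal(tr, grid, retention, loadm, rng_disp,
                                             stops_per_day=config.stops_per_day,
                                             settle_days=config.settle_days,
                                             feed_probability_init=guava_frac))
            event_frames.append(events_to_frame(ev, repeat=rep))
        except Exception as e:
            raise StageError("dispersal", e) from e
        if rep == 0:
            for tr in trajs:
                for k, (x, y) in enumerate(tr.positions):
                    traj_rows.append((tr.individual_id, k, x, y))
    pd.DataFrame(traj_rows, columns=["individual_id", "step_index", "x", "y"]).to_csv(
        out / "trajectories_rep0.csv", index=False)
    if until == "trajectories":
        return _write_manifest(out, config)
    events = pd.concat(event_frames, ignore_index=True)
    events.to_csv(out / "events.csv", index=False)

    # ---- seed rain + fate -----------------------------------------------
    try:
        rain = accumulate_seed_rain(event_frames, grid)
        rain.per_cell.to_csv(out / "seed_rain.csv")
        fate = apply_fate_mask(rain, grid)
        fate.per_cell.to_csv(out / "seed_fate.csv")
    except Exception as e:
        raise StageError("fate", e) from e
    if until in ("dispersal", "fate"):
        return _write_manifest(out, config)

    # ---- validation -----------------------------------------------------
    try:
        summary: dict = {"n_events": int(len(events)),
                         "total_seeds": int(rain.total_seeds),
                         "germinable_seeds": int(fate.total_seeds)}
        tables = summarize_deposition(events, grid)
        for name, tab in tables.items():
            tab.to_csv(out / f"deposition_{name}.csv", index=False)
        if len(dung) and len(events):
            obs = dung[dung["contains_guava"]]["elevation"]
            ks = ks_compare(obs, events["elevation"])
            summary["ks_observed_vs_simulated"] = {"D": ks.D, "p": ks.p,
                                                   "n_obs": ks.n1, "n_sim": ks.n2}
        (out / "validation.json").write_text(json.dumps(summary, indent=1))
    except Exception as e:
        raise StageError("validate", e) from e

    return _write_manifest(out, config)
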