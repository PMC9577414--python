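"""Seed fate, deposition summaries and simulated-vs-observed validation.

Seed fate restricts the simulated seed rain to cells where a binary
establishment-suitability mask (a thresholded species distribution model,
supplied as an input layer) predicts germination success. Validation compares
the elevation distribution of simulated seed-bearing dung piles against
observed records with two-sample Kolmogorov–Smirnov tests, and summarises
deposition by landcover class and management zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .grid import HexGrid
from .gut import SeedRain


@dataclass
class DungPileRecord:
    """One dung-pile observation (field survey or simulation output)."""

    x: float
    y: float
    elevation: float
    contains_guava: bool
    landcover: str
    zone: str
    source: str  # "observed" | "simulated"


@dataclass
class SeedFate:
    """Germinable seed density: seed rain masked by establishment suitability."""

    per_cell: pd.DataFrame  # index cell_id; columns seeds, suitable

    @property
    def total_seeds(self) -> int:
        return int(self.per_cell["seeds"].sum())


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


def apply_fate_mask(rain: SeedRain, grid: HexGrid) -> SeedFate:
    """Elementwise product of seed rain with the binary suitability mask."""
    suitable = grid.cells["suitable"].astype(bool)
    if suitable.isna().any():
        raise ValueError("suitability mask undefined on some cells")
    seeds = rain.per_cell["seeds"].reindex(grid.cells.index, fill_value=0)
    return SeedFate(pd.DataFrame({"seeds": seeds.where(suitable, 0),
                                  "suitable": suitable}))


def summarize_deposition(events: pd.DataFrame, grid: HexGrid,
                         elevation_bin_m: float = 50.0) -> dict[str, pd.DataFrame]:
    """Counts and fractions of excretion events by landcover, zone and
    elevation bin (and per repeat where a ``repeat`` column is present)."""
    if events.empty:
        warn("no excretion events to summarise", stacklevel=2)
        return {"landcover": pd.DataFrame(), "zone": pd.DataFrame(),
                "elevation": pd.DataFrame()}
    ev = events.copy()
    ev["landcover"] = grid.cells["landcover"].reindex(ev["cell_id"]).to_numpy()
    ev["zone"] = grid.cells["zone"].reindex(ev["cell_id"]).to_numpy()

    def _table(col):
        counts = ev.groupby(col).size().rename("count").reset_index()
        counts["fraction"] = counts["count"] / counts["count"].sum()
        return counts

    emax = float(ev["elevation"].max())
    edges = np.arange(0.0, emax + elevation_bin_m, elevation_bin_m)
    ebin = pd.cut(ev["elevation"], edges, include_lowest=True)
    keys = ["repeat", ebin] if "repeat" in ev.columns else [ebin]
    elev = ev.groupby(keys, observed=False).size().rename("count").reset_index()
    return {"landcover": _table("landcover"), "zone": _table("zone"),
            "elevation": elev}


def ks_compare(sample_a, sample_b, min_n: int = 5) -> KSResult:
    """Two-sample KS test (asymptotic p) between two elevation samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"both samples need >= {min_n} values")
    res = ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), len(a), len(b))


def stop_sensitivity(runs: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise KS comparison of event elevations across stops-per-day runs.

    ``runs`` maps stops_per_day to a pooled event table (all repeats). Runs
    must come from the same landscape and trajectory set so that only the
    within-day stop interpolation differs.
    """
    keys = sorted(runs)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            r = ks_compare(runs[ka]["elevation"], runs[kb]["elevation"])
            rows.append({"stops_a": ka, "stops_b": kb, "D": r.D, "p": r.p,
                         "n_a": r.n1, "n_b": r.n2})
    return pd.DataFrame(rows)


def elevation_density(sample, grid_pts: np.ndarray | None = None,
                      bw_method: str = "silverman"):
    """Gaussian-KDE frequency density of event elevations (per-repeat curves
    for the stochastic envelope are obtained by calling this per repeat)."""
    from scipy.stats import gaussian_kde
    a = np.asarray(sample, dtype=float)
    kde = gaussian_kde(a, bw_method=bw_method)
    if grid_pts is None:
        grid_pts = np.linspace(a.min() - 50, a.max() + 50, 256)
    return grid_pts, kde(grid_pts)
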