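"""Foraging, gut retention and excretion of seeds along simulated migrations.

Gut passage is modelled with a right-skewed normal retention-time
distribution: the probability R_d that a seed eaten d days ago is excreted
today is the Fernandez–Steel two-piece skew-normal density (standardised to a
given mean and standard deviation, skewness parameter xi) evaluated at the
integer day d, truncated at d_max days after which seeds are assumed to have
left the gut. Combining R with a binary feeding history F over the last
d_max days gives the excretion probability

    P_g = sum_d R_d F_d / sum_d R_d .

Each excretion event deposits a seed count drawn from a truncated normal
seed-load distribution. Events accumulated over individuals and stochastic
repeats form the population-level "seed rain".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .ertg import SimTrajectory
from .grid import HexGrid


def skew_normal_density(x, mean: float, sd: float, xi: float):
    """Fernandez–Steel two-piece skew-normal density, standardised so the
    distribution has the requested mean and sd; xi > 1 skews right."""
    m1 = 2.0 / np.sqrt(2.0 * np.pi)
    mu = m1 * (xi - 1.0 / xi)
    sigma = np.sqrt((1.0 - m1**2) * (xi**2 + 1.0 / xi**2) + 2.0 * m1**2 - 1.0)
    z = (np.asarray(x, dtype=float) - mean) / sd
    zz = z * sigma + mu
    scale = np.where(zz >= 0, xi, 1.0 / xi)
    return 2.0 / (xi + 1.0 / xi) * norm.pdf(zz / scale) * sigma / sd


@dataclass
class RetentionModel:
    """Gut retention-time model; defaults from tortoise feeding trials."""

    mean_days: float = 12.0
    sd_days: float = 8.0
    skewness: float = 2.0
    d_max: int = 28
    R: np.ndarray = field(init=False)

    def __post_init__(self):
        d = np.arange(1, self.d_max + 1)
        self.R = skew_normal_density(d, self.mean_days, self.sd_days, self.skewness)

    def retention_probability(self, d: int) -> float:
        """R_d: probability of excreting today a seed eaten d days ago."""
        if d < 1 or int(d) != d:
            raise ValueError("d must be an integer >= 1")
        return float(self.R[d - 1]) if d <= self.d_max else 0.0

    def excretion_probability(self, history: np.ndarray) -> float:
        """P_g for a binary feeding history (entry d-1 = ate d days ago)."""
        F = np.asarray(history)
        if F.shape != (self.d_max,):
            raise ValueError(f"history must have length {self.d_max}")
        if not np.isin(F, (0, 1)).all():
            raise ValueError("history entries must be 0/1")
        return float((self.R * F).sum() / self.R.sum())

    def init_history(self, feed_probability: float, rng: np.random.Generator) -> np.ndarray:
        """I.i.d. Bernoulli pre-simulation feeding history of length d_max."""
        if not 0.0 <= feed_probability <= 1.0:
            raise ValueError("feed_probability must be in [0, 1]")
        return (rng.random(self.d_max) < feed_probability).astype(np.int8)


@dataclass
class SeedLoadModel:
    """Seeds per excretion event: truncated normal, rounded, floor at 1."""

    count_mean: float = 1443.0
    count_sd: float = 2057.0
    lower: float = 1.0

    def sample(self, rng: np.random.Generator, size=None):
        a = (self.lower - self.count_mean) / self.count_sd
        draw = truncnorm.rvs(a, np.inf, loc=self.count_mean, scale=self.count_sd,
                             size=size, random_state=rng)
        return np.maximum(np.rint(draw), self.lower).astype(int)

    def analytic_mean(self) -> float:
        a = (self.lower - self.count_mean) / self.count_sd
        return float(truncnorm.mean(a, np.inf, loc=self.count_mean, scale=self.count_sd))


@dataclass
class ExcretionEvent:
    individual_id: str
    day: int
    x: float
    y: float
    cell_id: int
    seed_count: int
    elevation: float


def _daily_stops(traj: SimTrajectory, stops_per_day: int) -> np.ndarray:
    """(n_steps, stops_per_day, 2) stop positions for migration days 1..n.

    Extra stops interpolate the day's movement segment; the last stop of each
    day is the day's end position. The origin day itself is not a stop — the
    time spent at the origin before departure is what the pre-simulation
    feeding history accounts for.
    """
    pos = traj.positions
    frac = np.arange(1, stops_per_day + 1) / stops_per_day  # last stop = segment end
    segs = pos[1:] - pos[:-1]
    return pos[:-1, None, :] + frac[None, :, None] * segs[:, None, :]


def simulate_dispersal(traj: SimTrajectory, grid: HexGrid,
                       retention: RetentionModel, load: SeedLoadModel,
                       rng: np.random.Generator,
                       stops_per_day: int = 1, settle_days: int | None = None,
                       feed_probability_init: float = 0.21) -> list[ExcretionEvent]:
    """Daily feeding/excretion along one trajectory.

    Each day the individual visits ``stops_per_day`` stop locations (obtained
    by interpolating the day's movement). Feeding: if any stop's cell carries
    the source plant, that day's feeding flag is 1. Excretion: every stop
    draws Bernoulli(P_g) independently, P_g computed from the feeding history
    of the preceding ``d_max`` days; on success a seed count is sampled and an
    event recorded at the stop. After arrival the individual remains at the
    destination for ``settle_days`` (default d_max) further days under the
    same rules, so late-ingested seeds can still be deposited.
    """
    if stops_per_day not in (1, 2, 4):
        raise ValueError("stops_per_day must be 1, 2 or 4")
    if not traj.converged:
        raise ValueError("trajectory did not converge")
    if settle_days is None:
        settle_days = retention.d_max

    stops = _daily_stops(traj, stops_per_day)
    if settle_days:
        tail = np.repeat(stops[-1:, -1:, :], settle_days, axis=0)
        tail = np.repeat(tail, stops_per_day, axis=1)
        stops = np.concatenate([stops, tail], axis=0)
    n_days = stops.shape[0]

    cids = grid.locate(stops[..., 0].ravel(), stops[..., 1].ravel()).reshape(
        n_days, stops_per_day)
    inside = cids >= 0
    if not inside.all():
        import warnings
        warnings.warn(f"{traj.individual_id}: stops outside grid skipped", stacklevel=2)
    guava_col = grid.cells["guava_present"].to_numpy(dtype=bool)
    elev_col = grid.cells["elevation"].to_numpy(dtype=float)
    pos_of = {cid: k for k, cid in enumerate(grid.cells.index)}
    rowix = np.array([pos_of[c] if c >= 0 else 0 for c in cids.ravel()]).reshape(cids.shape)
    ate_stop = guava_col[rowix] & inside
    ate_day = ate_stop.any(axis=1).astype(np.int8)

    # feeding history is independent of excretion, so P_g is precomputable:
    # ext holds the pre-simulation history (reversed) then each simulated
    # day's feeding flag; row i of `stops` is simulation day i + 1
    dmax = retention.d_max
    history = retention.init_history(feed_probability_init, rng)
    ext = np.concatenate([history[::-1], ate_day])
    pg = np.zeros(n_days)
    for d in range(1, dmax + 1):
        pg += retention.R[d - 1] * ext[dmax - d:dmax - d + n_days]
    pg /= retention.R.sum()

    u = rng.random((n_days, stops_per_day))
    hit = inside & (u < pg[:, None])
    n_hits = int(hit.sum())
    counts = load.sample(rng, size=n_hits) if n_hits else np.array([], dtype=int)
    events: list[ExcretionEvent] = []
    for k, (day, s) in enumerate(zip(*np.nonzero(hit))):
        cid = int(cids[day, s])
        events.append(ExcretionEvent(traj.individual_id, int(day) + 1,
                                     float(stops[day, s, 0]), float(stops[day, s, 1]),
                                     cid, int(counts[k]), float(elev_col[rowix[day, s]])))
    return events


def events_to_frame(events: list[ExcretionEvent], repeat: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame([e.__dict__ for e in events],
                      columns=["individual_id", "day", "x", "y", "cell_id",
                               "seed_count", "elevation"])
    if repeat is not None:
        df["repeat"] = repeat
    return df


@dataclass
class SeedRain:
    """Per-cell seed deposition accumulated over simulation repeats."""

    per_cell: pd.DataFrame      # index cell_id; columns seeds, events
    per_repeat: pd.DataFrame    # columns repeat, cell_id, seeds
    n_simulations: int

    @property
    def total_seeds(self) -> int:
        return int(self.per_cell["seeds"].sum())


def accumulate_seed_rain(event_frames: list[pd.DataFrame], grid: HexGrid) -> SeedRain:
    """Sum excretion events into per-cell seed rain, keeping per-repeat layers
    so the stochastic envelope across repeats stays inspectable."""
    if not event_frames:
        raise ValueError("need at least one simulation repeat")
    frames = [df.assign(repeat=i) if "repeat" not in df.columns else df
              for i, df in enumerate(event_frames)]
    allev = pd.concat(frames, ignore_index=True)
    per_cell = pd.DataFrame(index=grid.cells.index)
    if len(allev):
        g = allev.groupby("cell_id")["seed_count"]
        per_cell["seeds"] = g.sum().reindex(grid.cells.index, fill_value=0)
        per_cell["events"] = g.size().reindex(grid.cells.index, fill_value=0)
        per_repeat = (allev.groupby(["repeat", "cell_id"])["seed_count"]
                      .sum().rename("seeds").reset_index())
    else:
        per_cell["seeds"] = 0
        per_cell["events"] = 0
        per_repeat = pd.DataFrame(columns=["repeat", "cell_id", "seeds"])
    return SeedRain(per_cell, per_repeat, len(event_frames))
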