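"""Empirical random trajectory generation between fixed endpoints.

The simulator reproduces the geometry of observed migration tracks. A fitted
:class:`MovementKernel` stores the empirical distributions of daily step
length and turning angle, their lag-1 autocorrelation structure, and the
step-turn covariance, all as binned histograms over the observed (step, turn)
atoms. Trajectory simulation is a two-part conditional walk:

1. an *unconstrained* biased-correlated random walk whose proposals are the
   observed (step, turn) pairs reweighted by the lag-1 conditional kernels —
   this preserves marginal and serial structure of the template; and
2. a *pull* term that multiplies each proposal's weight by the probability
   that the remaining k steps of an unconstrained walk could still cover the
   remaining distance to the destination (estimated from pre-simulated
   k-step displacement distributions).

The product makes the walk mean-reverting towards the destination, in the
manner of a discrete Ornstein-Uhlenbeck bridge, while every realised step and
turn remains inside the empirical support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import MigrantAssignment
from .grid import HexGrid
from .movement import Track

TWO_PI = 2.0 * np.pi
N_TURN_BINS = 36
PULL_WALKS = 500          # unconstrained walks pre-simulated per kernel
PULL_BINS = 24
PULL_FLOOR = 1e-4         # keeps the pull density strictly positive on support


def _wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % TWO_PI - np.pi)


def _fd_bins(x: np.ndarray) -> np.ndarray:
    """Freedman–Diaconis bin edges with sane fallbacks for tiny samples."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2.0 * iqr / len(x) ** (1 / 3) if iqr > 0 else (hi - lo) / 10.0
    nbins = int(np.clip(np.ceil((hi - lo) / width), 12, 60))
    return np.linspace(lo, hi, nbins + 1)


def _row_normalise(mat: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    sm = mat + alpha
    return sm / sm.sum(axis=1, keepdims=True)


@dataclass
class MovementKernel:
    """Empirical movement geometry of one template track (daily resolution)."""

    source_track_id: str
    steps: np.ndarray                 # observed daily step lengths, m
    turns: np.ndarray                 # observed turning angles, rad in (-pi, pi]
    step_edges: np.ndarray = field(init=False)
    turn_edges: np.ndarray = field(init=False)
    step_hist: np.ndarray = field(init=False)
    turn_hist: np.ndarray = field(init=False)
    lag1_step: np.ndarray = field(init=False)     # P(step bin | previous step bin)
    lag1_turn: np.ndarray = field(init=False)     # P(turn bin | previous turn bin)
    step_turn_cov: np.ndarray = field(init=False)  # joint (step bin, turn bin) freq
    _pull_tables: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=float)
        self.turns = _wrap_angle(np.asarray(self.turns, dtype=float))
        if len(self.steps) < 10:
            raise ValueError("kernel needs a track with at least 10 daily steps")
        self.step_edges = _fd_bins(self.steps)
        self.turn_edges = np.linspace(-np.pi, np.pi, N_TURN_BINS + 1)
        self.step_hist, _ = np.histogram(self.steps, self.step_edges, density=False)
        self.step_hist = self.step_hist / self.step_hist.sum()
        self.turn_hist, _ = np.histogram(self.turns, self.turn_edges, density=False)
        self.turn_hist = self.turn_hist / self.turn_hist.sum()

        sb = self._step_bin(self.steps)
        tb = self._turn_bin(self.turns)
        # frequency-table representation keeps per-bin empirical means so the
        # binned kernel reproduces the track's moments exactly
        centers = (self.step_edges[:-1] + self.step_edges[1:]) / 2.0
        self.step_bin_means = centers.copy()
        for b in np.unique(sb):
            self.step_bin_means[b] = self.steps[sb == b].mean()
        ns, nt = len(self.step_hist), N_TURN_BINS
        lag_s = np.zeros((ns, ns))
        np.add.at(lag_s, (sb[:-1], sb[1:]), 1.0)
        self.lag1_step = _row_normalise(lag_s)
        lag_t = np.zeros((nt, nt))
        np.add.at(lag_t, (tb[:-1], tb[1:]), 1.0)
        self.lag1_turn = _row_normalise(lag_t)
        cov = np.zeros((ns, nt))
        # turns[i] is the turn *into* step i+1: pair step[i+1] with turn[i]
        np.add.at(cov, (sb[1:], tb), 1.0)
        self.step_turn_cov = (cov + 0.5) / (cov + 0.5).sum()

        # proposal atoms: consecutive (step, turn-into-step) pairs
        self._atom_steps = self.steps[1:]
        self._atom_turns = self.turns
        self._atom_sb = sb[1:]
        self._atom_tb = tb
        # per-state proposal weights W[s_prev_bin, t_prev_bin, atom], precomputed
        ps = np.maximum(self.step_hist[self._atom_sb], 1e-12)
        pt = np.maximum(self.turn_hist[self._atom_tb], 1e-12)
        self._W = (self.lag1_step[:, self._atom_sb][:, None, :]
                   * self.lag1_turn[:, self._atom_tb][None, :, :]) / (ps * pt)
        csum = np.cumsum(self._W, axis=2)
        self._Wcdf = csum / csum[:, :, -1:]

    # -- helpers -----------------------------------------------------------

    def _step_bin(self, s):
        return np.clip(np.searchsorted(self.step_edges, s, side="right") - 1,
                       0, len(self.step_hist) - 1)

    def _turn_bin(self, t):
        return np.clip(np.searchsorted(self.turn_edges, t, side="right") - 1,
                       0, N_TURN_BINS - 1)

    @property
    def median_step(self) -> float:
        return float(np.median(self.steps))

    @property
    def mean_step(self) -> float:
        """Mean daily step from the binned representation (frequency-weighted
        per-bin means)."""
        return float((self.step_hist * self.step_bin_means).sum())

    def circular_mean_turn(self) -> float:
        return float(np.arctan2(np.sin(self.turns).mean(), np.cos(self.turns).mean()))

    def _atom_weights(self, prev_sb: int, prev_tb: int) -> np.ndarray:
        """eRTG proposal weights for each atom given the lag-1 state.

        Atoms are drawn from the empirical (step, turn) joint, so reweighting
        by P(s|s_prev)P(t|t_prev) / (P(s)P(t)) yields the product kernel of
        conditional step, conditional turn and step-turn covariance.
        """
        return self._W[prev_sb, prev_tb]

    # -- unconstrained walk & pull tables ---------------------------------

    def _walks_unconstrained(self, n_walks: int, n_steps: int,
                             rng: np.random.Generator) -> np.ndarray:
        """Free CRW realisations, vectorised across walks.

        Returns (n_walks, n_steps, 2) positions relative to a common origin.
        """
        pos = np.zeros((n_walks, 2))
        heading = rng.uniform(-np.pi, np.pi, n_walks)
        sb = np.full(n_walks, self._step_bin(self.median_step))
        tb = np.full(n_walks, self._turn_bin(0.0))
        out = np.zeros((n_walks, n_steps, 2))
        for k in range(n_steps):
            cdf = self._Wcdf[sb, tb]                      # (n_walks, n_atoms)
            idx = (cdf < rng.random((n_walks, 1))).sum(axis=1)
            heading = _wrap_angle(heading + self._atom_turns[idx])
            pos = pos + self._atom_steps[idx, None] * np.column_stack(
                [np.cos(heading), np.sin(heading)])
            out[:, k] = pos
            sb, tb = self._atom_sb[idx], self._atom_tb[idx]
        return out

    def prepare_pull(self, k_max: int, rng: np.random.Generator) -> None:
        """Pre-simulate free walks and tabulate k-step displacement densities."""
        have = max(self._pull_tables) if self._pull_tables else 0
        if k_max <= have:
            return
        walks = self._walks_unconstrained(PULL_WALKS, k_max, rng)
        disp = np.hypot(walks[..., 0], walks[..., 1])
        for k in range(1, k_max + 1):
            edges = np.linspace(0.0, max(disp[:, k - 1].max(), self.median_step) * 1.05,
                                PULL_BINS + 1)
            hist, _ = np.histogram(disp[:, k - 1], edges, density=True)
            self._pull_tables[k] = (edges, hist + PULL_FLOOR * hist.max() + 1e-300)

    def pull_density(self, dist: np.ndarray, k_remaining: int) -> np.ndarray:
        """Density of covering ``dist`` in ``k_remaining`` free steps."""
        edges, hist = self._pull_tables[k_remaining]
        idx = np.searchsorted(edges, dist, side="right") - 1
        out = np.zeros_like(np.asarray(dist, dtype=float))
        ok = (idx >= 0) & (idx < len(hist))
        out[ok] = hist[idx[ok]]
        return out


def fit_movement_kernel(track: Track, projection=None) -> MovementKernel:
    """Fit the empirical movement kernel from a daily-thinned track."""
    proj = projection or track.local_projection()
    xy = track.xy(proj)
    if len(xy) < 11:
        raise ValueError("need at least 10 steps (11 daily fixes) to fit a kernel")
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = _wrap_angle(np.diff(headings))
    return MovementKernel(track.individual_id, steps, turns)


def fit_kernel_from_xy(track_id: str, xy: np.ndarray) -> MovementKernel:
    """Kernel from planar daily positions (synthetic pipelines skip lon/lat)."""
    d = np.diff(np.asarray(xy, dtype=float), axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    turns = _wrap_angle(np.diff(np.arctan2(d[:, 1], d[:, 0])))
    return MovementKernel(track_id, steps, turns)


@dataclass
class SimTrajectory:
    """One simulated daily migration between assigned endpoints."""

    individual_id: str
    positions: np.ndarray       # (n_steps + 1, 2) planar metres
    origin_cell: int
    dest_cell: int
    n_steps: int
    converged: bool
    template_track_id: str
    presnap_miss_m: float = np.nan

    def __post_init__(self):
        if self.positions.shape != (self.n_steps + 1, 2):
            raise ValueError("positions must be (n_steps + 1, 2)")


def choose_n_steps(origin_xy, dest_xy, kernel: MovementKernel) -> int:
    """Number of daily steps: travel distance over median daily displacement."""
    dist = float(np.hypot(*(np.asarray(dest_xy, float) - np.asarray(origin_xy, float))))
    med = kernel.median_step
    if med <= 0:
        raise ValueError("kernel has non-positive median step")
    return max(2, int(round(dist / med)))


def simulate_trajectory(origin_xy, dest_xy, n_steps: int, kernel: MovementKernel,
                        rng: np.random.Generator,
                        snap_tol: float | None = None) -> SimTrajectory:
    """Simulate one fixed-length trajectory between two endpoints.

    Returns a trajectory with ``converged=False`` if the walk's final position
    misses the destination by more than the snap tolerance (default: half the
    kernel's median daily displacement); callers retry with a new template.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    origin = np.asarray(origin_xy, dtype=float)
    dest = np.asarray(dest_xy, dtype=float)
    eps = snap_tol if snap_tol is not None else 0.5 * kernel.median_step
    kernel.prepare_pull(n_steps, rng)

    pos = np.zeros((n_steps + 1, 2))
    pos[0] = origin
    to_dest = dest - origin
    heading = float(np.arctan2(to_dest[1], to_dest[0]))
    sb = kernel._step_bin(kernel.median_step)
    tb = kernel._turn_bin(0.0)
    cos, sin = np.cos, np.sin
    for k in range(1, n_steps + 1):
        w = kernel._atom_weights(sb, tb)
        headings = _wrap_angle(heading + kernel._atom_turns)
        endpoints = pos[k - 1] + (kernel._atom_steps[:, None]
                                  * np.column_stack([cos(headings), sin(headings)]))
        resid = np.hypot(*(dest - endpoints).T)
        k_rem = n_steps - k
        if k_rem == 0:
            pull = np.where(resid <= eps, 1.0, 0.0)
        else:
            pull = kernel.pull_density(resid, k_rem)
        w = w * pull
        tot = w.sum()
        if tot <= 0 or not np.isfinite(tot):
            # dead end: no proposal can still reach the destination
            return SimTrajectory(kernel.source_track_id, np.zeros((n_steps + 1, 2)),
                                 -1, -1, n_steps, False, kernel.source_track_id)
        idx = rng.choice(len(w), p=w / tot)
        heading = headings[idx]
        pos[k] = endpoints[idx]
        sb, tb = kernel._atom_sb[idx], kernel._atom_tb[idx]

    miss = float(np.hypot(*(dest - pos[-1])))
    converged = miss <= eps
    if converged:
        pos[-1] = dest  # snap
    return SimTrajectory("", pos, -1, -1, n_steps, converged,
                         kernel.source_track_id, presnap_miss_m=miss)


def run_population(assignments: list[MigrantAssignment], kernels: list[MovementKernel],
                   grid: HexGrid, rng: np.random.Generator,
                   max_attempts: int = 100) -> list[SimTrajectory]:
    """Simulate one converged trajectory per origin–destination assignment.

    For each individual a template kernel is picked uniformly at random (with
    replacement); on non-convergence another template is drawn, up to
    ``max_attempts`` per individual before a hard error.
    """
    if not kernels:
        raise ValueError("need at least one movement kernel")
    out = []
    xy = grid.cells[["x", "y"]]
    for a in assignments:
        origin = xy.loc[a.origin_cell].to_numpy(dtype=float)
        dest = xy.loc[a.dest_cell].to_numpy(dtype=float)
        traj = None
        for _ in range(max_attempts):
            kern = kernels[rng.integers(len(kernels))]
            n_steps = choose_n_steps(origin, dest, kern)
            cand = simulate_trajectory(origin, dest, n_steps, kern, rng)
            if cand.converged:
                traj = cand
                break
        if traj is None:
            raise RuntimeError(
                f"no template converged for {a.individual_id} "
                f"({a.origin_cell}->{a.dest_cell}) after {max_attempts} attempts")
        traj.individual_id = a.individual_id
        traj.origin_cell = a.origin_cell
        traj.dest_cell = a.dest_cell
        out.append(traj)
    return out
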