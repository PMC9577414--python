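"""Migratory connectivity as a Monge–Kantorovich transportation problem.

Seasonal energy distributions (NDVI-weighted highland supply H and lowland
supply L, each rescaled to the migrating population size) are connected by the
minimum-cost flow

    minimise   sum_ij c_ij f_ij
    subject to f_ij >= 0                          (one-way flow)
               sum_j f_ij <= k_hi                 (highland energy demand)
               sum_i f_ij <= k_lj                 (lowland energy supply)
               sum_ij f_ij = min(sum k_h, sum k_l)  (move as much as possible)

with c_ij the centroid distance (km) between cells — an optimal-redistribution
model of connectivity equivalent to the Earth Mover's Distance between H and
L. The LP is solved exactly with HiGHS; optimal flows are integerised into
per-individual origin–destination assignments by largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .grid import HexGrid
from .movement import SeasonalRange

MASS_TOL = 1e-6


@dataclass
class SeasonalDistribution:
    """Per-cell energy weights for one season."""

    season: str
    cell_ids: np.ndarray   # (n,) int
    weights: np.ndarray    # (n,) float, >= 0

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.cell_ids) != len(self.weights):
            raise ValueError("cell_ids and weights length mismatch")
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValueError("weights must be finite and non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("total weight must be positive")

    @property
    def total(self) -> float:
        return float(self.weights.sum())


@dataclass
class FlowMatrix:
    """Optimal flows between highland rows and lowland columns."""

    flows: np.ndarray          # (m, n), f_ij >= 0
    origin_cells: np.ndarray   # (m,) highland cell_ids
    dest_cells: np.ndarray     # (n,) lowland cell_ids
    costs: np.ndarray          # (m, n) cost matrix (km)
    total_cost: float

    @property
    def grand_total(self) -> float:
        return float(self.flows.sum())

    def to_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(self.flows > MASS_TOL)
        return pd.DataFrame({
            "origin_cell": self.origin_cells[i],
            "dest_cell": self.dest_cells[j],
            "flow": self.flows[i, j],
        })


@dataclass
class MigrantAssignment:
    individual_id: str
    origin_cell: int
    dest_cell: int


def energy_from_ndvi(grid: HexGrid, srange: SeasonalRange,
                     population_size: int) -> SeasonalDistribution:
    """Seasonal energy distribution from NDVI.

    Weight per cell is proportional to max(NDVI, 0) x cell area, rescaled so
    the weights sum exactly to ``population_size`` — the migrating population
    the flow model will generate.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    cell_ids = np.array(sorted(srange.member_cells), dtype=int)
    ndvi = grid.cells.loc[cell_ids, "ndvi"].to_numpy(dtype=float)
    w = np.clip(ndvi, 0.0, None) * grid.area_km2
    if w.sum() <= 0:
        raise ValueError(f"all-zero NDVI in {srange.season} range")
    w = w * (population_size / w.sum())
    return SeasonalDistribution(srange.season, cell_ids, w)


def transport_cost(grid: HexGrid, H: SeasonalDistribution,
                   L: SeasonalDistribution) -> np.ndarray:
    """Relocation cost matrix: centroid-to-centroid distance in km."""
    ch = grid.cells.loc[H.cell_ids, ["x", "y"]].to_numpy(dtype=float)
    cl = grid.cells.loc[L.cell_ids, ["x", "y"]].to_numpy(dtype=float)
    return cdist(ch, cl) / 1000.0


def solve_transport(H: SeasonalDistribution, L: SeasonalDistribution,
                    costs: np.ndarray) -> FlowMatrix:
    """Exact LP solution of the transportation problem (no distance threshold).

    Raises if the solver fails; the returned flows satisfy the four
    constraints to within ``MASS_TOL``.
    """
    m, n = len(H.cell_ids), len(L.cell_ids)
    costs = np.asarray(costs, dtype=float)
    if costs.shape != (m, n):
        raise ValueError("cost matrix shape mismatch")
    if not np.isfinite(costs).all():
        raise ValueError("cost matrix must be finite")

    total = min(H.total, L.total)
    # variables x = vec(F) row-major; rows: supply caps, demand caps; one equality
    A_ub = np.zeros((m + n, m * n))
    for i in range(m):
        A_ub[i, i * n:(i + 1) * n] = 1.0
    for j in range(n):
        A_ub[m + j, j::n] = 1.0
    b_ub = np.concatenate([H.weights, L.weights])
    res = linprog(costs.ravel(), A_ub=A_ub, b_ub=b_ub,
                  A_eq=np.ones((1, m * n)), b_eq=[total],
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    F = np.clip(res.x.reshape(m, n), 0.0, None)
    return FlowMatrix(F, H.cell_ids.copy(), L.cell_ids.copy(), costs,
                      float((costs * F).sum()))


def _largest_remainder(flows_flat: np.ndarray, population_size: int) -> np.ndarray:
    base = np.floor(flows_flat).astype(int)
    short = population_size - base.sum()
    if short < 0:  # numerical guard; flows sum to the population by contract
        raise ValueError("flows exceed population size")
    rema = flows_flat - base
    # deterministic tie-break: larger remainder first, then lower index
    order = np.lexsort((np.arange(len(rema)), -rema))
    base[order[:short]] += 1
    return base


def assign_individuals(flow: FlowMatrix, population_size: int,
                       rng: np.random.Generator | None = None,
                       stochastic: bool = False) -> list[MigrantAssignment]:
    """Integerise optimal flows into individual origin->destination pairs.

    Largest-remainder rounding (default) keeps every integer count within 1 of
    its fractional flow and sums exactly to ``population_size``. A multinomial
    alternative (``stochastic=True``) resamples counts proportional to flow.
    """
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    if abs(flow.grand_total - population_size) > 1e-3 * max(1.0, population_size):
        raise ValueError("grand total flow does not match population size")
    flat = flow.flows.ravel() * (population_size / flow.grand_total)
    if stochastic:
        if rng is None:
            raise ValueError("stochastic integerisation needs an rng")
        counts = rng.multinomial(population_size, flat / flat.sum())
    else:
        counts = _largest_remainder(flat, population_size)
    counts = counts.reshape(flow.flows.shape)
    out = []
    k = 0
    for i, j in zip(*np.nonzero(counts)):
        for _ in range(int(counts[i, j])):
            out.append(MigrantAssignment(f"sim_{k:05d}",
                                         int(flow.origin_cells[i]),
                                         int(flow.dest_cells[j])))
            k += 1
    return out
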