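import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migraseed import (SeasonalRange, assign_individuals, energy_from_ndvi,
                       solve_transport, transport_cost)
from migraseed.connectivity import SeasonalDistribution
from migraseed.grid import HexGrid


def dist(season, weights, ids=None):
    ids = np.arange(len(weights)) if ids is None else ids
    return SeasonalDistribution(season, ids, np.asarray(weights, dtype=float))


# ---------------------------------------------------------------- oracles

def brute_force_cost(supply, demand, costs):
    """Exhaustive integer enumeration (optimal is integral for integer data)."""
    m, n = costs.shape
    total = min(sum(supply), sum(demand))
    def rows(cap):
        vals = range(cap + 1)
        return [v for v in itertools.product(vals, repeat=n) if sum(v) <= cap]
    best = np.inf
    for combo in itertools.product(*[rows(s) for s in supply]):
        F = np.array(combo)
        if F.sum() != total or (F.sum(axis=0) > demand).any():
            continue
        best = min(best, float((F * costs).sum()))
    return best


def network_simplex_cost(supply, demand, costs, scale=10**6):
    """Independent min-cost-flow oracle (networkx) on the balanced instance."""
    import networkx as nx
    S, D = sum(supply), sum(demand)
    G = nx.DiGraph()
    for i, s in enumerate(supply):
        G.add_node(("h", i), demand=-int(s))
    for j, d in enumerate(demand):
        G.add_node(("l", j), demand=int(d))
    for i in range(len(supply)):
        for j in range(len(demand)):
            G.add_edge(("h", i), ("l", j), weight=int(round(costs[i, j] * scale)))
    # slack absorbs only the imbalance side, so min(S, D) units must cross
    if S != D:
        G.add_node("slack", demand=int(S) - int(D))
        if S > D:
            for i in range(len(supply)):
                G.add_edge(("h", i), "slack", weight=0)
        else:
            for j in range(len(demand)):
                G.add_edge("slack", ("l", j), weight=0)
    cost, _ = nx.network_simplex(G)
    return cost / scale


# ---------------------------------------------------------------- energy

def _uniform_grid(n=16):
    g = HexGrid.covering_box(-3000, -3000, 3000, 3000, 1.18)
    g.cells["ndvi"] = 0.5
    return g


def test_energy_uniform_ndvi_splits_evenly():
    g = _uniform_grid()
    ids = set(g.cells.index[:4])
    d = energy_from_ndvi(g, SeasonalRange("highland", ids), population_size=8)
    assert d.weights == pytest.approx([2.0] * 4)


def test_energy_total_is_population_size_exactly():
    g = _uniform_grid()
    g.cells["ndvi"] = np.random.default_rng(0).uniform(0.1, 0.9, g.n_cells)
    d = energy_from_ndvi(g, SeasonalRange("lowland", set(g.cells.index)), 1000)
    assert d.total == pytest.approx(1000.0, abs=1e-9)


def test_energy_proportional_to_ndvi():
    g = _uniform_grid()
    ids = list(g.cells.index[:2])
    g.cells.loc[ids, "ndvi"] = [0.2, 0.4]
    d = energy_from_ndvi(g, SeasonalRange("highland", set(ids)), 3)
    assert sorted(d.weights) == pytest.approx([1.0, 2.0])


def test_energy_all_zero_ndvi_rejected():
    g = _uniform_grid()
    g.cells["ndvi"] = 0.0
    with pytest.raises(ValueError, match="NDVI"):
        energy_from_ndvi(g, SeasonalRange("highland", set(g.cells.index[:3])), 10)


# ---------------------------------------------------------------- costs

def test_cost_zero_iff_same_cell_and_symmetric():
    g = _uniform_grid()
    ids = np.asarray(g.cells.index[:5])
    H = dist("highland", np.ones(5), ids)
    L = dist("lowland", np.ones(5), ids)
    C = transport_cost(g, H, L)
    assert np.allclose(np.diag(C), 0.0)
    assert np.allclose(C, C.T)
    assert (C[~np.eye(5, dtype=bool)] > 0).all()


def test_cost_is_centroid_distance_km():
    g = _uniform_grid()
    H = dist("highland", [1.0], np.asarray([g.cells.index[0]]))
    L = dist("lowland", [1.0], np.asarray([g.cells.index[1]]))
    expect = np.hypot(*(g.cells.iloc[0][["x", "y"]].to_numpy()
                        - g.cells.iloc[1][["x", "y"]].to_numpy())) / 1000.0
    assert transport_cost(g, H, L)[0, 0] == pytest.approx(expect)


def test_cost_triangle_inequality_random_triples():
    g = _uniform_grid()
    rng = np.random.default_rng(5)
    ids = np.asarray(g.cells.index)
    all_ = dist("highland", np.ones(len(ids)), ids)
    C = transport_cost(g, all_, dist("lowland", np.ones(len(ids)), ids))
    for _ in range(200):
        a, b, c = rng.choice(len(ids), 3, replace=False)
        assert C[a, c] <= C[a, b] + C[b, c] + 1e-9


# ---------------------------------------------------------------- solver

def test_single_route():
    C = np.array([[2.5]])
    f = solve_transport(dist("highland", [5.0]), dist("lowland", [5.0]), C)
    assert f.flows[0, 0] == pytest.approx(5.0)
    assert f.total_cost == pytest.approx(12.5)


def test_unbalanced_moves_min_of_totals():
    C = np.ones((2, 2))
    f = solve_transport(dist("highland", [6.0, 4.0]), dist("lowland", [3.0, 4.0]), C)
    assert f.grand_total == pytest.approx(7.0, abs=1e-6)


def test_3x3_matches_exhaustive_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(5):
        supply = rng.integers(1, 5, 3)
        demand = rng.integers(1, 5, 3)
        C = rng.integers(1, 10, (3, 3)).astype(float)
        f = solve_transport(dist("highland", supply), dist("lowland", demand), C)
        assert f.total_cost == pytest.approx(brute_force_cost(supply, demand, C), abs=1e-8)


def test_solver_matches_network_simplex_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        m, n = rng.integers(1, 5, 2)
        supply = rng.integers(1, 10, m)
        demand = rng.integers(1, 10, n)
        C = rng.integers(1, 100, (m, n)).astype(float)
        f = solve_transport(dist("highland", supply), dist("lowland", demand), C)
        oracle = network_simplex_cost(supply, demand, C)
        assert f.total_cost == pytest.approx(oracle, rel=1e-8, abs=1e-8)


def test_constraints_and_swap_optimality():
    rng = np.random.default_rng(31)
    supply = rng.uniform(0.5, 3.0, 4)
    demand = rng.uniform(0.5, 3.0, 4)
    C = rng.uniform(1.0, 10.0, (4, 4))
    f = solve_transport(dist("highland", supply), dist("lowland", demand), C)
    assert (f.flows >= -1e-9).all()
    assert (f.flows.sum(axis=1) <= supply + 1e-6).all()
    assert (f.flows.sum(axis=0) <= demand + 1e-6).all()
    assert f.grand_total == pytest.approx(min(supply.sum(), demand.sum()), abs=1e-6)
    used = np.argwhere(f.flows > 1e-7)
    for (i, j), (i2, j2) in itertools.combinations(map(tuple, used), 2):
        if i != i2 and j != j2:
            assert C[i, j2] + C[i2, j] >= C[i, j] + C[i2, j2] - 1e-7


def test_degenerate_single_sink_takes_everyone():
    C = np.array([[1.0], [5.0], [2.0]])
    f = solve_transport(dist("highland", [3, 3, 4]), dist("lowland", [10.0]), C)
    assigns = assign_individuals(f, 10)
    assert len(assigns) == 10
    assert all(a.dest_cell == 0 for a in assigns)


# ---------------------------------------------------------------- integerisation

def test_assignment_exact_integer_flows():
    C = 2.0 * np.ones((2, 2)) - np.eye(2)
    f = solve_transport(dist("highland", [2.0, 3.0]), dist("lowland", [2.0, 3.0]), C)
    assigns = assign_individuals(f, 5)
    assert len(assigns) == 5
    pairs = {(a.origin_cell, a.dest_cell) for a in assigns}
    assert pairs == {(0, 0), (1, 1)}


@given(st.lists(st.floats(0.01, 10.0, allow_nan=False), min_size=1, max_size=24),
       st.integers(1, 200))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_largest_remainder_invariants(weights, pop):
    """Counts sum exactly to the population and each stays within 1 of its
    fractional flow, for arbitrary positive flow patterns."""
    from migraseed.connectivity import _largest_remainder
    flows = np.asarray(weights)
    flows = flows * (pop / flows.sum())
    counts = _largest_remainder(flows, pop)
    assert counts.sum() == pop
    assert (np.abs(counts - flows) < 1.0).all()


def test_assignment_rounding_bound_random_trials():
    rng = np.random.default_rng(99)
    from migraseed.connectivity import FlowMatrix
    for _ in range(100):
        m, n = rng.integers(1, 6, 2)
        F = rng.uniform(0, 3, (m, n))
        pop = max(1, int(round(F.sum())))
        F *= pop / F.sum()
        fm = FlowMatrix(F, np.arange(m), np.arange(n), np.zeros((m, n)), 0.0)
        assigns = assign_individuals(fm, pop)
        assert len(assigns) == pop
        counts = np.zeros((m, n))
        for a in assigns:
            counts[a.origin_cell, a.dest_cell] += 1
        assert (np.abs(counts - F) < 1.0).all()
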