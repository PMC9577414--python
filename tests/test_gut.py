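import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from migraseed import (RetentionModel, SeedLoadModel, SimTrajectory,
                       accumulate_seed_rain, events_to_frame, simulate_dispersal)
from migraseed.grid import HexGrid
from migraseed.gut import _daily_stops


# ---------------------------------------------------------------- oracle

def skewnorm_oracle(x, mean, sd, xi):
    """Independent two-piece skew-normal density: standardisation constants
    obtained by numerical integration rather than closed form."""
    def f(z):
        return (2.0 / (xi + 1.0 / xi)) * (norm.pdf(z / xi) if z >= 0 else norm.pdf(z * xi))
    m = quad(lambda z: z * f(z), -20, 60)[0]
    v = quad(lambda z: z * z * f(z), -20, 60)[0] - m * m
    s = np.sqrt(v)
    z = (x - mean) / sd * s + m
    return f(z) * s / sd


# ---------------------------------------------------------------- retention

def test_retention_beyond_threshold_is_zero_and_d_validated():
    rm = RetentionModel()
    assert rm.retention_probability(29) == 0.0
    assert rm.retention_probability(28) > 0.0
    with pytest.raises(ValueError):
        rm.retention_probability(0)


def test_retention_density_matches_numerical_oracle():
    rm = RetentionModel()
    for d in (1, 5, 12, 20, 28):
        assert rm.retention_probability(d) == pytest.approx(
            skewnorm_oracle(d, 12.0, 8.0, 2.0), abs=1e-6)


def test_right_skew_longer_upper_tail():
    rm = RetentionModel()
    mode = 1 + int(np.argmax(rm.R))
    assert mode < rm.mean_days  # right skew: mode below the mean


# ---------------------------------------------------------------- P_g

def test_pg_zero_full_and_single_day():
    rm = RetentionModel()
    assert rm.excretion_probability(np.zeros(28, dtype=int)) == 0.0
    assert rm.excretion_probability(np.ones(28, dtype=int)) == pytest.approx(1.0)
    h = np.zeros(28, dtype=int)
    h[4] = 1  # fed 5 days ago
    expect = skewnorm_oracle(5, 12.0, 8.0, 2.0) / sum(
        skewnorm_oracle(d, 12.0, 8.0, 2.0) for d in range(1, 29))
    assert rm.excretion_probability(h) == pytest.approx(expect, rel=1e-6)


def test_pg_monotone_under_feeding_flips(rng):
    rm = RetentionModel()
    for _ in range(50):
        h = (rng.random(28) < 0.3).astype(int)
        base = rm.excretion_probability(h)
        zeros = np.flatnonzero(h == 0)
        if len(zeros):
            h2 = h.copy()
            h2[rng.choice(zeros)] = 1
            assert rm.excretion_probability(h2) >= base


def test_init_history_bernoulli():
    rm = RetentionModel()
    rng = np.random.default_rng(2)
    assert rm.init_history(0.0, rng).sum() == 0
    assert rm.init_history(1.0, rng).sum() == 28
    draws = np.concatenate([rm.init_history(0.21, rng) for _ in range(3600)])
    assert draws.mean() == pytest.approx(0.21, abs=0.004)


# ---------------------------------------------------------------- seed load

def test_seed_counts_truncated_normal():
    load = SeedLoadModel()
    rng = np.random.default_rng(3)
    x = load.sample(rng, size=100_000)
    assert (x >= 1).all()
    assert x.mean() == pytest.approx(load.analytic_mean(), rel=0.01)
    assert np.array_equal(load.sample(np.random.default_rng(3), size=10),
                          load.sample(np.random.default_rng(3), size=10))


# ---------------------------------------------------------------- dispersal

def _toy_grid(guava: str):
    """9x9 km grid; 'none' | 'origin' | 'everywhere' source-plant layouts."""
    g = HexGrid.covering_box(-4500, -4500, 4500, 4500, 1.18)
    g.cells["elevation"] = 100.0
    g.cells["ndvi"] = 0.5
    g.cells["guava_present"] = guava == "everywhere"
    if guava == "origin":
        g.cells.loc[g.locate(-3000.0, 0.0), "guava_present"] = True
    return g


def _toy_traj(n_steps=10):
    x = np.linspace(-3000, 3000, n_steps + 1)
    pos = np.column_stack([x, np.zeros(n_steps + 1)])
    return SimTrajectory("tort", pos, 0, 1, n_steps, True, "tmpl")


def test_no_guava_no_history_no_events(rng):
    ev = simulate_dispersal(_toy_traj(), _toy_grid("none"), RetentionModel(),
                            SeedLoadModel(), rng, feed_probability_init=0.0)
    assert ev == []


def test_guava_everywhere_full_history_excretes_every_stop(rng):
    traj = _toy_traj(10)
    ev = simulate_dispersal(traj, _toy_grid("everywhere"), RetentionModel(),
                            SeedLoadModel(), rng, settle_days=5,
                            feed_probability_init=1.0)
    # P_g = 1 throughout: one event per daily stop, including the settle phase
    assert len(ev) == 10 + 5
    assert all(e.seed_count >= 1 for e in ev)


def test_single_feeding_day_mode_matches_retention_mode(rng):
    """Feeding only at the first stop's cell on day 1: excretion-day lags
    follow the retention distribution, so the modal lag sits at its mode."""
    rm = RetentionModel()
    # wide-spaced stops so each daily stop falls in a distinct hex cell
    x = -7000.0 + 1400.0 * np.arange(11)
    pos = np.column_stack([x, np.zeros(11)])
    traj = SimTrajectory("tort", pos, 0, 1, 10, True, "tmpl")
    grid = HexGrid.covering_box(-8500, -4500, 8500, 4500, 1.18)
    grid.cells["elevation"] = 100.0
    grid.cells["guava_present"] = False
    stop1 = traj.positions[1]
    grid.cells.loc[grid.locate(*stop1), "guava_present"] = True
    # make sure only day 1's stop is in that cell
    cells_visited = [int(grid.locate(*p)) for p in traj.positions[1:]]
    assert cells_visited.count(int(grid.locate(*stop1))) == 1
    lags = []
    for _ in range(1500):
        ev = simulate_dispersal(traj, grid, rm, SeedLoadModel(), rng,
                                settle_days=28, feed_probability_init=0.0)
        lags.extend(e.day - 1 for e in ev)
    counts = np.bincount(lags, minlength=29)[1:29].astype(float)
    freq = counts / counts.sum()
    expected = rm.R / rm.R.sum()
    # lag distribution reproduces the retention density bin by bin
    assert np.abs(freq - expected).max() < 0.02
    # smoothed empirical mode lies on the analytic near-mode plateau
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    plateau = np.flatnonzero(rm.R >= 0.95 * rm.R.max()) + 1
    emp_mode = int(np.argmax(smooth)) + 1
    assert plateau.min() - 2 <= emp_mode <= plateau.max() + 2


def test_stops_interpolation_geometry():
    traj = _toy_traj(3)
    stops = _daily_stops(traj, 2)
    assert stops.shape == (3, 2, 2)
    assert np.allclose(stops[0, 1], traj.positions[1])    # last stop = day end
    assert np.allclose(stops[0, 0], (traj.positions[0] + traj.positions[1]) / 2)
    assert np.allclose(stops[-1, 1], traj.positions[-1])  # arrival at destination


def test_unconverged_trajectory_rejected(rng):
    tr = _toy_traj(5)
    tr.converged = False
    with pytest.raises(ValueError):
        simulate_dispersal(tr, _toy_grid("none"), RetentionModel(), SeedLoadModel(), rng)


# ---------------------------------------------------------------- seed rain

def test_seed_rain_conservation_and_additivity(rng):
    grid = _toy_grid("everywhere")
    f1 = events_to_frame(simulate_dispersal(_toy_traj(), grid, RetentionModel(),
                                            SeedLoadModel(), rng,
                                            feed_probability_init=1.0))
    f2 = events_to_frame(simulate_dispersal(_toy_traj(), grid, RetentionModel(),
                                            SeedLoadModel(), rng,
                                            feed_probability_init=1.0))
    rain = accumulate_seed_rain([f1, f2], grid)
    assert rain.total_seeds == f1["seed_count"].sum() + f2["seed_count"].sum()
    assert rain.n_simulations == 2
    only1 = accumulate_seed_rain([f1], grid)
    assert only1.total_seeds == f1["seed_count"].sum()


def test_single_event_lands_in_right_cell():
    import pandas as pd
    grid = _toy_grid("none")
    cid = int(grid.locate(0.0, 0.0))
    df = pd.DataFrame([{"individual_id": "a", "day": 0, "x": 0.0, "y": 0.0,
                        "cell_id": cid, "seed_count": 100, "elevation": 100.0}])
    rain = accumulate_seed_rain([df], grid)
    assert rain.per_cell.loc[cid, "seeds"] == 100
    assert rain.per_cell["seeds"].sum() == 100
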