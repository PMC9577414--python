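import numpy as np
import pandas as pd
import pytest

from migraseed import IslandConfig, Track, generate_island


@pytest.fixture(scope="session")
def island():
    """Default synthetic island (seed 0), with observed-style dung piles."""
    return generate_island(IslandConfig())


@pytest.fixture(scope="session")
def island_kernels(island):
    """Movement kernels fitted from the island's migration-phase tracks."""
    from migraseed import fit_kernel_from_xy
    kernels = []
    for t in island.migration_tracks():
        x, y = island.projection.forward(t.fixes["lon"].to_numpy(),
                                         t.fixes["lat"].to_numpy())
        kernels.append(fit_kernel_from_xy(t.individual_id, np.column_stack([x, y])))
    return kernels


def make_track(xy, start="2020-01-01 00:00", freq="D", individual_id="t0", proj=None,
               **extra_cols):
    """Track from planar metre coordinates via a local projection at (0, 0)."""
    from migraseed import LocalProjection
    proj = proj or LocalProjection(0.0, 0.0)
    xy = np.asarray(xy, dtype=float)
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    fixes = pd.DataFrame({
        "timestamp": pd.date_range(start, periods=len(xy), freq=freq),
        "lon": lon, "lat": lat, **extra_cols,
    })
    return Track(individual_id, fixes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
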