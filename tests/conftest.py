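import numpy as np
import pytest

import sealusage as su


@pytest.fixture(scope="session")
def small_world():
    """A 40x40 synthetic seascape with grouped haul-out sites."""
    return su.gen_world(
        nrows=40, ncols=40, land_fraction=0.25, n_sites=8, n_groups=5,
        total_population=200, survey_coverage=0.9, seed=7,
    )


@pytest.fixture(scope="session")
def small_tracks(small_world):
    fixes, meta = su.simulate_tracks(small_world, n_animals=10, mean_lifespan_h=500.0, seed=11)
    return fixes, meta


@pytest.fixture(scope="session")
def prepared(small_world, small_tracks):
    fixes, _ = small_tracks
    tracks, assoc, excl = su.prepare(fixes, small_world.grid)
    return tracks, assoc, excl


@pytest.fixture(scope="session")
def open_sea_grid():
    """A 30x30 grid that is entirely sea."""
    return su.GridSpec(30, 30, np.zeros((30, 30), bool))
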