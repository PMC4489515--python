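import numpy as np
import pytest

import otternet as ot


@pytest.fixture(scope="session")
def toy_world():
    """400-point straight coastline with several latrines and a spawning
    patch; core lengths scaled down so female cores fit the 4-km line."""
    net, _init, behav = ot.toy_line_world(
        400, latrine_ids=[50, 100, 150, 200, 250, 300, 350],
        spawn_ids=[200, 201, 202])
    init = ot.InitParams(density_min=5, density_max=5,
                         out_of_area_factor=0.0,
                         female_core_mean_km=0.5, female_core_sd_km=0.25)
    return net, init, behav


@pytest.fixture(scope="session")
def toy_log(toy_world):
    """200-hour replicate on the toy world (compiled engine)."""
    net, init, behav = toy_world
    return ot.run_replicate(net, ot.get_scenario("School_100%"), init,
                            behav, seed=3, n_hours=200)


@pytest.fixture(scope="session")
def latrine_rich_net():
    """2,000-point line where every point is latrine-grade (distinct MEP)."""
    n = 2000
    mep = 0.5 + 0.4 * np.linspace(0, 1, n)
    coords = np.column_stack([np.arange(n) * 10.0, np.zeros(n)])
    return ot.LandscapeNetwork(
        coords=coords, mep=mep, radial_scale=np.ones(n),
        spawn_habitat=np.zeros(n, dtype=bool),
        in_study_area=np.ones(n, dtype=bool),
        on_virtual_line=np.zeros(n, dtype=bool),
        edges=[(i, i + 1, 10.0) for i in range(n - 1)])


@pytest.fixture(scope="session")
def small_synthetic_net():
    """A 40-km synthetic coastline with corridors, for structural tests."""
    return ot.generate_synthetic_landscape(40.0, 8.0, 0.58, 0.2, 2.0, seed=7)
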