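import numpy as np
import pandas as pd
import pytest

import mobimeter as mm


@pytest.fixture(scope="session")
def world_small():
    """Two-city noise-free-friendly world: exact tower grid, one park+mall."""
    cfg = mm.WorldConfig(n_cities=2, n_days=4, n_users_per_city=60,
                         towers_per_city=16, tower_jitter=0.0,
                         n_parks=1, n_malls=1, facility_size=3000.0, seed=42)
    return mm.gen_world(cfg)


@pytest.fixture(scope="session")
def aqi_small(world_small):
    return mm.gen_aqi(world_small.config, "wave")


@pytest.fixture(scope="session")
def noiseless_run(world_small, aqi_small):
    """Choices, true positions and noiseless (k=1) logs for the small world."""
    rng = np.random.default_rng(1)
    choices = mm.gen_choices(world_small.truth, aqi_small, world_small.homes,
                             rng=rng)
    positions = mm.true_positions(world_small, choices, rng=rng)
    records = mm.gen_logs(world_small, positions, mm.LogNoise(k=1), rng=rng)
    return {"choices": choices, "positions": positions, "records": records}


@pytest.fixture(scope="session")
def geo_small(noiseless_run, world_small):
    return mm.geolocate(noiseless_run["records"], world_small.towers)


@pytest.fixture(scope="session")
def sim_panel():
    """Study-layout panel (6 cities x 4 days x 16 h, 5000 users/city) drawn
    from a known continuous-AQI truth."""
    cfg = mm.WorldConfig(seed=7)
    rng = np.random.default_rng(7)
    truth = mm.default_truth(cfg, rng, measure="aqi")
    aqi = mm.gen_aqi(cfg, "wave")
    panel = mm.gen_panel_counts(truth, aqi, 5000, rng)
    return {"config": cfg, "truth": truth, "aqi": aqi, "panel": panel}


@pytest.fixture(scope="session")
def sim_panel_levels():
    """Same layout with a level-dummy truth (for level-switch effects)."""
    cfg = mm.WorldConfig(seed=8)
    rng = np.random.default_rng(8)
    truth = mm.default_truth(cfg, rng, measure="levels")
    aqi = mm.gen_aqi(cfg, "wave")
    panel = mm.gen_panel_counts(truth, aqi, 5000, rng)
    return {"config": cfg, "truth": truth, "aqi": aqi, "panel": panel}


def toy_records(rows):
    """records frame from (phone, tower, ts, event) tuples."""
    return pd.DataFrame(rows, columns=["phone_id", "tower_id", "timestamp",
                                       "event"])
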