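import numpy as np
import pytest

from nitroplan import (
    SyntheticConfig,
    calibrate_delta,
    cost_baseline,
    estimate_elasticities,
    estimate_sur,
    generate_district_panel,
    generate_household_sample,
    generate_toy_rasters,
)


@pytest.fixture(scope="session")
def cfg_small():
    return SyntheticConfig(seed=11, n_districts=4)


@pytest.fixture(scope="session")
def panel_small(cfg_small):
    return generate_district_panel(cfg_small)


@pytest.fixture(scope="session")
def hh_small(cfg_small, panel_small):
    return generate_household_sample(cfg_small, panel_small)


@pytest.fixture(scope="session")
def yparams_small(hh_small, panel_small):
    params = estimate_elasticities(hh_small)
    calibrate_delta(panel_small, params)
    return params


@pytest.fixture(scope="session")
def cost_small(panel_small):
    return cost_baseline(panel_small)


@pytest.fixture(scope="session")
def rasters_small(cfg_small):
    return generate_toy_rasters(cfg_small)


@pytest.fixture(scope="session")
def cfg_national():
    """Full-size (64-district) generating configuration."""
    return SyntheticConfig(seed=3, n_districts=64)


@pytest.fixture(scope="session")
def panel_national(cfg_national):
    return generate_district_panel(cfg_national)


@pytest.fixture(scope="session")
def sur_national(panel_national):
    return estimate_sur(panel_national.share_dataset())


@pytest.fixture(scope="session")
def panel_opt():
    """Mid-size panel for optimizer tests, with calibrated yield params."""
    cfg = SyntheticConfig(seed=5, n_districts=8)
    panel = generate_district_panel(cfg)
    hh = generate_household_sample(cfg, panel)
    params = estimate_elasticities(hh)
    calibrate_delta(panel, params)
    return panel, params


def random_pit_free_dem(rng: np.random.Generator, rows: int = 8, cols: int = 8):
    """Monotone-drainage DEM: base south-tilted plane plus bounded noise so
    every pixel keeps a strictly lower neighbor in the row below."""
    base = (rows - 1 - np.arange(rows))[:, None] * np.ones((1, cols))
    return base + rng.uniform(-0.4, 0.4, size=(rows, cols))
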