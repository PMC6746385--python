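import numpy as np
import pytest
import xarray as xr

from epicens import ClimateProfile, generate_world, make_preset
from epicens.simulator import run_ensemble


@pytest.fixture(scope="session")
def small_world():
    return generate_world(n_cells=24, n_countries=6, n_years=12, seed=11)


@pytest.fixture(scope="session")
def noiseless_world():
    return generate_world(
        n_cells=8, n_countries=3, n_years=12, seed=2,
        climate_profile=ClimateProfile.noiseless(),
    )


@pytest.fixture()
def iiasa():
    return make_preset("iiasa")


@pytest.fixture()
def gepic():
    return make_preset("gepic")


@pytest.fixture(scope="session")
def small_cube(small_world):
    """Two-member ensemble over the harmonized scenarios (shared, heavy)."""
    configs = [make_preset("iiasa"), make_preset("gepic")]
    return run_ensemble(
        small_world, configs,
        scenarios=("fullharm", "harm-suffN"),
        water_regimes=("rainfed", "irrigated"),
    )


def make_random_cube(rng, n_configs=3, n_years=10, n_cells=6,
                     scenarios=("fullharm",), waters=("rainfed", "irrigated")):
    """Small random yield cube with the canonical dimensions."""
    data = rng.uniform(
        0.5, 8.0, size=(n_configs, len(scenarios), len(waters), n_years, n_cells)
    )
    return xr.DataArray(
        data,
        dims=("config", "scenario", "water", "year", "cell"),
        coords={
            "config": [f"m{i}" for i in range(n_configs)],
            "scenario": list(scenarios),
            "water": list(waters),
            "year": np.arange(1, n_years + 1),
            "cell": np.arange(n_cells),
        },
        name="yield",
        attrs={"units": "t ha-1"},
    )
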