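"""Area-weighted aggregation of grid-cell yields to countries and the globe.

The national average for country c is

    YD_av,c = sum_g (YD_i,g * HA_i,g + YD_r,g * HA_r,g)
              / sum_g (HA_i,g + HA_r,g)

over the country's grid cells g, with irrigated (i) and rainfed (r) yields
weighted by the respective harvested areas.  Areas are static across years;
missing cell-years are excluded with the weights renormalized.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import DataError

__all__ = [
    "aggregate_national",
    "aggregate_national_array",
    "aggregate_global",
    "national_table",
    "ensemble_mean_series",
]

logger = logging.getLogger(__name__)


def _weighted_series(values: np.ndarray, w_irr: np.ndarray, w_rf: np.ndarray,
                     water_labels: list[str]) -> np.ndarray:
    """Eq-1 combination for one cell subset.

    ``values`` has shape (n_water, n_years, n_cells); weights (n_cells,).
    NaN cell-years are dropped with weight renormalization.
    """
    i_irr = water_labels.index("irrigated")
    i_rf = water_labels.index("rainfed")
    w = np.stack([np.zeros_like(w_irr)] * len(water_labels))
    w[i_irr] = w_irr
    w[i_rf] = w_rf
    w3 = w[:, None, :]  # (water, 1, cell)
    valid = np.isfinite(values)
    num = np.nansum(np.where(valid, values, 0.0) * w3, axis=(0, 2))
    den = np.sum(np.where(valid, w3, 0.0), axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def _select(cube: xr.DataArray, config=None, scenario=None) -> xr.DataArray:
    sub = cube
    if config is not None:
        sub = sub.sel(config=config)
    if scenario is not None:
        sub = sub.sel(scenario=scenario)
    extra = [d for d in sub.dims if d not in ("water", "year", "cell")]
    if extra:
        raise DataError(
            f"cube still has dimensions {extra}; select config/scenario first"
        )
    return sub.transpose("water", "year", "cell")


def aggregate_national_array(cube: xr.DataArray, world) -> dict[int, np.ndarray]:
    """National yearly series per country id from a (water, year, cell) cube."""
    sub = _select(cube)
    if "rainfed" not in list(sub["water"].values) or "irrigated" not in list(
        sub["water"].values
    ):
        raise DataError("cube must contain both water regimes")
    vals = sub.values
    labels = [str(w) for w in sub["water"].values]
    out: dict[int, np.ndarray] = {}
    for cid in sorted(world.countries):
        idx = world.cells_of_country(cid)
        if len(idx) == 0:
            continue
        w_irr = world.area_irrigated[idx]
        w_rf = world.area_rainfed[idx]
        if np.sum(w_irr + w_rf) <= 0:
            warnings.warn(f"country {cid} has zero harvested area; dropped")
            continue
        out[cid] = _weighted_series(vals[:, :, idx], w_irr, w_rf, labels)
    return out


def aggregate_national(cube: xr.DataArray, world, config=None, scenario=None) -> pd.DataFrame:
    """Tidy national series (country_id, year, yield) for one config/scenario."""
    series = aggregate_national_array(_select(cube, config, scenario), world)
    years = cube["year"].values
    rows = [
        {"country_id": cid, "year": int(y), "yield": float(v)}
        for cid, vec in series.items()
        for y, v in zip(years, vec)
    ]
    return pd.DataFrame(rows)


def aggregate_global(cube: xr.DataArray, world, config=None, scenario=None) -> np.ndarray:
    """Global area-weighted yearly series (all cells as one region)."""
    sub = _select(cube, config, scenario)
    vals = sub.values
    labels = [str(w) for w in sub["water"].values]
    return _weighted_series(vals, world.area_irrigated, world.area_rainfed, labels)


def national_table(cube: xr.DataArray, world) -> pd.DataFrame:
    """National series for every (config, scenario) in the cube."""
    frames = []
    configs = [str(c) for c in np.atleast_1d(cube["config"].values)] if "config" in cube.dims else [None]
    scenarios = [str(s) for s in np.atleast_1d(cube["scenario"].values)] if "scenario" in cube.dims else [None]
    for cfg in configs:
        for scen in scenarios:
            df = aggregate_national(cube, world, config=cfg, scenario=scen)
            df["config"] = cfg
            df["scenario"] = scen
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ensemble_mean_series(series_by_config: np.ndarray, alpha: float = 0.05):
    """Per-year ensemble mean and t-based confidence interval of the mean.

    ``series_by_config`` has shape (n_configs, n_years).  Returns
    (mean, lower, upper); with a single config the CI bounds are NaN.
    """
    arr = np.asarray(series_by_config, dtype=float)
    if arr.ndim != 2:
        raise DataError("expected a (config, year) array")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n < 2:
        nanv = np.full(arr.shape[1], np.nan)
        return mean, nanv, nanv
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    return mean, mean - tcrit * sem, mean + tcrit * sem
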