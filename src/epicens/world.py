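"""Synthetic gridded agro-environment.

Generates the study region every downstream stage runs on: grid cells with
daily weather (seasonal sinusoid + autocorrelated noise on a 360-day
calendar of 12 x 30-day months), layered soils, N/P application rates,
rainfed/irrigated harvested areas, country and climate-region labels,
growing-season dates and heat-unit requirements — plus country-level
"reported" yield series with a technology trend, noise and data-quality
flags.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import xarray as xr

from .config import ConfigurationError, default_cultivars
from .errors import DataError
from .seeding import derive_rng

__all__ = [
    "DAYS_PER_YEAR",
    "N_SOIL_LAYERS",
    "ClimateProfile",
    "GridCellEnv",
    "WorldData",
    "ReportedYieldSeries",
    "assign_climate_region",
    "generate_world",
    "generate_reported_yields",
]

DAYS_PER_YEAR = 360  # 12 months of 30 days; no leap years
N_SOIL_LAYERS = 4

CLIMATE_REGIONS = ("tropical", "arid", "temperate", "cold")

# generation targets cycled over cells (interleaved so even small worlds
# cover every region)
_REGION_CYCLE = (
    "temperate tropical arid cold temperate tropical arid temperate cold "
    "tropical temperate arid temperate tropical cold temperate temperate "
    "tropical arid temperate"
).split()
_REGION_SPECS = {
    #            lat range      MAP range [mm]  temp offset [degC]
    "tropical": ((-12.0, 12.0), (900.0, 2000.0), 3.0),
    "arid": ((-35.0, 35.0), (130.0, 380.0), 2.0),
    "temperate": ((30.0, 48.0), (500.0, 1500.0), 0.0),
    "cold": ((50.0, 62.0), (420.0, 900.0), -2.0),
}


@dataclass(frozen=True)
class ClimateProfile:
    """Stochastic structure of the weather generator.

    With all noise terms zero and ``precip_stochastic`` False the weather is
    exactly the deterministic seasonal sinusoid.
    """

    temp_noise_sd: float = 1.6
    temp_ar1: float = 0.7
    srad_noise_sd: float = 2.5
    precip_stochastic: bool = True
    wet_day_prob: float = 0.35

    @classmethod
    def noiseless(cls) -> "ClimateProfile":
        return cls(temp_noise_sd=0.0, srad_noise_sd=0.0, precip_stochastic=False)


@dataclass
class GridCellEnv:
    """One grid cell: weather, soil, management, areas, labels.

    Weather arrays are views over the whole simulated period
    (``n_years * 360`` days); soil arrays have one entry per layer.
    """

    cell_id: int
    lat: float
    country_id: int
    climate_region: str
    mean_annual_precip: float
    tmin: np.ndarray
    tmax: np.ndarray
    srad: np.ndarray
    precip: np.ndarray
    layer_thickness: np.ndarray  # m
    field_capacity: np.ndarray  # mm per layer
    wilting_point: np.ndarray  # mm per layer
    ksat: np.ndarray  # mm/d per layer
    organic_n: np.ndarray  # kg/ha per layer
    mineral_n: np.ndarray  # kg/ha per layer
    labile_p: np.ndarray  # kg/ha per layer
    n_rate: float  # kg N/ha/yr
    p_rate: float  # kg P/ha/yr
    area_rainfed: float  # ha
    area_irrigated: float  # ha
    planting_doy: int
    harvest_doy: int
    phu: float  # degC d


@dataclass
class WorldData:
    """The synthetic study region (column-oriented storage).

    2-D arrays are (n_cells, n_days) for weather and (n_cells, n_layers)
    for soils.  ``GridCellEnv`` views are available through :meth:`cell`.
    """

    n_cells: int
    n_years: int
    seed: int
    lat: np.ndarray
    country_id: np.ndarray
    climate_region: np.ndarray  # unicode array
    mean_annual_precip: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    srad: np.ndarray
    precip: np.ndarray
    layer_thickness: np.ndarray
    field_capacity: np.ndarray
    wilting_point: np.ndarray
    ksat: np.ndarray
    organic_n: np.ndarray
    mineral_n: np.ndarray
    labile_p: np.ndarray
    n_rate: np.ndarray
    p_rate: np.ndarray
    area_rainfed: np.ndarray
    area_irrigated: np.ndarray
    planting_doy: np.ndarray
    harvest_doy: np.ndarray
    phu: np.ndarray
    countries: dict[int, str] = field(default_factory=dict)
    country_dev: dict[int, float] = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return self.n_years * DAYS_PER_YEAR

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)

    def cell(self, i: int) -> GridCellEnv:
        return GridCellEnv(
            cell_id=i,
            lat=float(self.lat[i]),
            country_id=int(self.country_id[i]),
            climate_region=str(self.climate_region[i]),
            mean_annual_precip=float(self.mean_annual_precip[i]),
            tmin=self.tmin[i],
            tmax=self.tmax[i],
            srad=self.srad[i],
            precip=self.precip[i],
            layer_thickness=self.layer_thickness[i],
            field_capacity=self.field_capacity[i],
            wilting_point=self.wilting_point[i],
            ksat=self.ksat[i],
            organic_n=self.organic_n[i],
            mineral_n=self.mineral_n[i],
            labile_p=self.labile_p[i],
            n_rate=float(self.n_rate[i]),
            p_rate=float(self.p_rate[i]),
            area_rainfed=float(self.area_rainfed[i]),
            area_irrigated=float(self.area_irrigated[i]),
            planting_doy=int(self.planting_doy[i]),
            harvest_doy=int(self.harvest_doy[i]),
            phu=float(self.phu[i]),
        )

    def cells(self) -> Iterator[GridCellEnv]:
        for i in range(self.n_cells):
            yield self.cell(i)

    def cells_of_country(self, country_id: int) -> np.ndarray:
        return np.flatnonzero(self.country_id == country_id)

    def validate(self) -> None:
        if np.any(self.field_capacity <= self.wilting_point):
            raise DataError("field_capacity must exceed wilting_point")
        if np.any(self.wilting_point < 0) or np.any(self.ksat <= 0):
            raise DataError("invalid soil hydraulic parameters")
        if np.any(self.area_rainfed + self.area_irrigated <= 0):
            raise DataError("every cell needs positive harvested area")
        if np.any(self.tmax < self.tmin):
            raise DataError("tmax < tmin")
        if np.any(self.precip < 0):
            raise DataError("negative precipitation")
        if np.any(self.phu <= 0):
            raise DataError("non-positive PHU")
        for cid in np.unique(self.country_id):
            if int(cid) not in self.countries:
                raise DataError(f"country {cid} missing from country table")


@dataclass
class ReportedYieldSeries:
    """Country-level annual reported yields with areas and quality flags."""

    country_id: int
    years: np.ndarray
    yields: np.ndarray  # t/ha
    harvested_area: np.ndarray  # ha
    fao_estimated_flag: bool
    production: np.ndarray  # t

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.yields) == len(self.harvested_area) == len(self.production) == n):
            raise DataError("reported series vectors must have equal length")
        if np.any(self.yields < 0) or np.any(self.harvested_area < 0):
            raise DataError("reported yields and areas must be >= 0")


def assign_climate_region(
    mean_annual_precip: float,
    mean_annual_temp: float,
    coldest_month: float | None = None,
    warmest_month: float | None = None,
) -> str:
    """Threshold-based climate region ("Koeppen-lite").

    tropical if the coldest-month mean is >= 18 degC and MAP >= 800 mm;
    arid if MAP < 400 mm; cold if the warmest-month mean is < 15 degC;
    temperate otherwise.  When monthly extremes are not supplied the annual
    mean is used for both.  At an exact threshold the rule written with the
    non-strict comparison wins (e.g. coldest == 18 is tropical, MAP == 400
    is not arid).
    """
    if not (np.isfinite(mean_annual_precip) and np.isfinite(mean_annual_temp)):
        raise DataError("climate inputs must be finite")
    cold_m = mean_annual_temp if coldest_month is None else coldest_month
    warm_m = mean_annual_temp if warmest_month is None else warmest_month
    if cold_m >= 18.0 and mean_annual_precip >= 800.0:
        return "tropical"
    if mean_annual_precip < 400.0:
        return "arid"
    if warm_m < 15.0:
        return "cold"
    return "temperate"


# ---------------------------------------------------------------------------
# weather pieces

def _season_cos(doy: np.ndarray, lat: float) -> np.ndarray:
    """Seasonal factor in [-1, 1]; +1 in the warm season of the hemisphere."""
    phase = -np.cos(2.0 * np.pi * (doy - 15.0) / DAYS_PER_YEAR)
    return phase if lat >= 0 else -phase


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho * rho, 1e-12)), size=n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = rho * acc + eps[i]
        out[i] = acc
    return out


def _temp_components(lat: float, offset: float) -> tuple[float, float]:
    """(annual mean, seasonal amplitude) of daily mean temperature."""
    mean = 27.5 - 0.52 * abs(lat) + offset
    amp = 1.2 + 0.26 * abs(lat)
    return mean, amp


def seasonal_temperature(lat: float, offset: float, doy: np.ndarray) -> np.ndarray:
    mean, amp = _temp_components(lat, offset)
    return mean + amp * _season_cos(doy, lat)


def seasonal_radiation(lat: float, doy: np.ndarray) -> np.ndarray:
    base = 22.0 - 0.12 * abs(lat)
    amp = 0.35 * base * (abs(lat) / 60.0 + 0.15)
    return np.maximum(base + amp * _season_cos(doy, lat), 0.5)


def seasonal_precip(lat: float, map_mm: float, doy: np.ndarray) -> np.ndarray:
    """Deterministic daily precipitation with warm-season concentration."""
    return (map_mm / DAYS_PER_YEAR) * (1.0 + 0.7 * _season_cos(doy, lat))


# ---------------------------------------------------------------------------

def generate_world(
    n_cells: int,
    n_countries: int,
    n_years: int,
    seed: int,
    climate_profile: ClimateProfile | None = None,
) -> WorldData:
    """Generate a deterministic synthetic study region.

    Requires ``n_years >= 12`` (detrending and evaluation-window logic) and
    ``n_cells >= n_countries``.  Weather is a latitude-dependent seasonal
    sinusoid plus AR(1) noise; N application rates span 0-300 kg/ha across
    cells, tied to a per-country development score.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if n_years < 12:
        raise ConfigurationError("n_years must be >= 12")
    if n_cells < n_countries:
        raise ConfigurationError("need at least one cell per country")
    profile = climate_profile or ClimateProfile()

    n_days = n_years * DAYS_PER_YEAR
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1.0

    lat = np.empty(n_cells)
    map_mm = np.empty(n_cells)
    offsets = np.empty(n_cells)
    targets = [_REGION_CYCLE[i % len(_REGION_CYCLE)] for i in range(n_cells)]
    rng_cells = derive_rng(seed, "world", "cells")
    for i, tgt in enumerate(targets):
        (lat_lo, lat_hi), (map_lo, map_hi), off = _REGION_SPECS[tgt]
        la = rng_cells.uniform(lat_lo, lat_hi)
        if tgt == "temperate" and rng_cells.random() < 0.3:
            la = -la  # some southern-hemisphere temperate cells
        lat[i] = la
        map_mm[i] = rng_cells.uniform(map_lo, map_hi)
        offsets[i] = off + rng_cells.normal(0.0, 0.5)

    # countries: contiguous blocks of cells; development score spans (0, 1)
    country_id = (np.arange(n_cells) * n_countries // n_cells).astype(np.int64)
    rng_cty = derive_rng(seed, "world", "countries")
    dev_values = (np.arange(n_countries) + 0.5) / n_countries
    rng_cty.shuffle(dev_values)
    countries = {k: f"country_{k:03d}" for k in range(n_countries)}
    country_dev = {k: float(dev_values[k]) for k in range(n_countries)}
    dev_cell = dev_values[country_id]

    # weather
    tmin = np.empty((n_cells, n_days))
    tmax = np.empty((n_cells, n_days))
    srad = np.empty((n_cells, n_days))
    precip = np.empty((n_cells, n_days))
    for i in range(n_cells):
        rng_w = derive_rng(seed, "world", "weather", i)
        tm = seasonal_temperature(lat[i], offsets[i], doy)
        tm = tm + _ar1(rng_w, n_days, profile.temp_ar1, profile.temp_noise_sd)
        dtr = rng_w.uniform(8.0, 14.0)
        tmin[i] = tm - dtr / 2.0
        tmax[i] = tm + dtr / 2.0
        sr = seasonal_radiation(lat[i], doy)
        if profile.srad_noise_sd > 0:
            sr = sr + _ar1(rng_w, n_days, 0.4, profile.srad_noise_sd)
        srad[i] = np.maximum(sr, 0.5)
        pr_det = seasonal_precip(lat[i], map_mm[i], doy)
        if profile.precip_stochastic:
            wet = rng_w.random(n_days) < profile.wet_day_prob
            amounts = rng_w.exponential(1.0, n_days)
            pr = np.where(wet, pr_det * amounts / profile.wet_day_prob, 0.0)
        else:
            pr = pr_det
        precip[i] = np.maximum(pr, 0.0)

    # soils
    rng_s = derive_rng(seed, "world", "soils")
    thickness = np.tile([0.25, 0.35, 0.50, 0.70], (n_cells, 1))
    theta_fc = rng_s.uniform(0.24, 0.36, size=(n_cells, 1)) + rng_s.uniform(
        -0.02, 0.02, size=(n_cells, N_SOIL_LAYERS)
    )
    theta_wp = theta_fc * rng_s.uniform(0.35, 0.55, size=(n_cells, N_SOIL_LAYERS))
    fc = theta_fc * thickness * 1000.0
    wp = theta_wp * thickness * 1000.0
    ksat = 10.0 ** rng_s.uniform(0.7, 2.3, size=(n_cells, N_SOIL_LAYERS))
    layer_w = np.array([0.45, 0.30, 0.15, 0.10])
    org_n = rng_s.uniform(3500.0, 8000.0, size=(n_cells, 1)) * layer_w
    min_n = rng_s.uniform(5.0, 25.0, size=(n_cells, 1)) * layer_w
    lab_p = (55.0 + 80.0 * dev_cell)[:, None] * layer_w

    # management
    rng_m = derive_rng(seed, "world", "management")
    n_rate = np.clip(dev_cell * 300.0 * rng_m.uniform(0.6, 1.3, n_cells), 0.0, 300.0)
    p_rate = n_rate * 0.15
    a_total = np.exp(rng_m.normal(7.0, 0.5, n_cells))
    irr_frac = rng_m.uniform(0.0, 0.6, n_cells) * dev_cell
    area_irrigated = a_total * irr_frac
    area_rainfed = a_total * (1.0 - irr_frac)

    # growing season (harmonized dates); southern seasons wrap the boundary
    north = lat >= 0
    plant = np.where(
        north,
        rng_m.integers(85, 111, n_cells),
        rng_m.integers(270, 301, n_cells),
    ).astype(np.int64)
    length = rng_m.integers(125, 166, n_cells)
    harvest = (plant + length - 1) % DAYS_PER_YEAR + 1

    # climate region from the realized deterministic climatology
    region = np.empty(n_cells, dtype="U9")
    for i in range(n_cells):
        mean, amp = _temp_components(lat[i], offsets[i])
        region[i] = assign_climate_region(
            map_mm[i], mean, coldest_month=mean - amp, warmest_month=mean + amp
        )

    # heat-unit requirement from the noiseless climatology over the season
    cv = default_cultivars()[1]
    phu = np.empty(n_cells)
    doy_year = np.arange(DAYS_PER_YEAR) + 1.0
    for i in range(n_cells):
        clim = seasonal_temperature(lat[i], offsets[i], doy_year)
        idx = _season_indices(int(plant[i]), int(harvest[i]))
        hu = np.clip(clim[idx - 1] - cv.t_base, 0.0, cv.t_opt - cv.t_base)
        phu[i] = max(float(hu.sum()), 1.0)

    world = WorldData(
        n_cells=n_cells,
        n_years=n_years,
        seed=seed,
        lat=lat,
        country_id=country_id,
        climate_region=region,
        mean_annual_precip=map_mm,
        tmin=tmin,
        tmax=tmax,
        srad=srad,
        precip=precip,
        layer_thickness=thickness,
        field_capacity=fc,
        wilting_point=wp,
        ksat=ksat,
        organic_n=org_n,
        mineral_n=min_n,
        labile_p=lab_p,
        n_rate=n_rate,
        p_rate=p_rate,
        area_rainfed=area_rainfed,
        area_irrigated=area_irrigated,
        planting_doy=plant,
        harvest_doy=harvest,
        phu=phu,
        countries=countries,
        country_dev=country_dev,
        generator_params={
            "n_cells": n_cells,
            "n_countries": n_countries,
            "n_years": n_years,
            "seed": seed,
            "climate_profile": vars(profile).copy(),
        },
    )
    world.validate()
    return world


def _season_indices(planting_doy: int, harvest_doy: int) -> np.ndarray:
    """Day-of-year indices of the season, wrapping the year boundary."""
    if harvest_doy >= planting_doy:
        return np.arange(planting_doy, harvest_doy + 1)
    return np.concatenate(
        [np.arange(planting_doy, DAYS_PER_YEAR + 1), np.arange(1, harvest_doy + 1)]
    )


# ---------------------------------------------------------------------------
# reported yields

def generate_reported_yields(
    world: WorldData,
    truth_cube: xr.DataArray,
    trend_slope: float = 0.0,
    noise_sd: float = 0.0,
    flag_fraction: float = 0.0,
    seed: int = 0,
    fluctuating_fraction: float = 0.0,
) -> dict[int, ReportedYieldSeries]:
    """Country "reported" yields from an area-aggregated truth cube.

    ``truth_cube`` must have dims (water, year, cell) for one configuration
    and scenario.  reported(c, y) = aggregated_truth(c, y)
    * (1 + trend_slope * (y - y0)) * (1 + eps), eps ~ N(0, noise_sd)
    truncated at -0.9 to keep yields positive.  ``flag_fraction`` of
    countries get the FAO-estimated flag; ``fluctuating_fraction`` get a
    harvested-area series fluctuating by more than 100 % (to exercise the
    country filter).
    """
    from .aggregation import aggregate_national_array

    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    for d in ("water", "year", "cell"):
        if d not in truth_cube.dims:
            raise DataError(f"truth cube missing dimension {d!r}")
    if truth_cube.sizes["cell"] != world.n_cells:
        raise DataError(
            "truth cube does not cover every grid cell (country coverage "
            "would be incomplete)"
        )

    years = truth_cube["year"].values
    national = aggregate_national_array(truth_cube, world)  # {cid: series}
    country_ids = sorted(world.countries)
    for cid in country_ids:
        if cid not in national:
            raise DataError(f"country {cid} missing from truth cube aggregate")

    rng = derive_rng(seed, "reported")
    flagged = set(
        int(c)
        for c in rng.choice(
            country_ids,
            size=int(round(flag_fraction * len(country_ids))),
            replace=False,
        )
    )
    fluctuating = set(
        int(c)
        for c in rng.choice(
            country_ids,
            size=int(round(fluctuating_fraction * len(country_ids))),
            replace=False,
        )
    )

    y0 = years[0]
    out: dict[int, ReportedYieldSeries] = {}
    for cid in country_ids:
        truth = np.nan_to_num(national[cid], nan=0.0)
        eps = rng.normal(0.0, noise_sd, size=len(years)) if noise_sd > 0 else np.zeros(len(years))
        eps = np.maximum(eps, -0.9)
        rep = truth * (1.0 + trend_slope * (years - y0)) * (1.0 + eps)
        idx = world.cells_of_country(cid)
        area_static = float(
            np.sum(world.area_rainfed[idx] + world.area_irrigated[idx])
        )
        area = np.full(len(years), area_static)
        if cid in fluctuating:
            area = area * np.where(np.arange(len(years)) % 2 == 0, 0.5, 1.5)
        out[cid] = ReportedYieldSeries(
            country_id=cid,
            years=np.asarray(years),
            yields=np.maximum(rep, 0.0),
            harvested_area=area,
            fao_estimated_flag=cid in flagged,
            production=np.maximum(rep, 0.0) * area,
        )
    return out
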