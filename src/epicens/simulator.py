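"""Minimal EPIC-style daily crop-soil simulator.

Process skeleton, per day of the growing season:

* phenology by accumulated heat units toward a per-cell requirement (PHU);
* canopy light interception from a logistic curve in heat-unit time;
* potential biomass gain from radiation-use efficiency (applied to half of
  incoming shortwave as the photosynthetically active fraction);
* a layered bucket water balance (curve-number runoff, conductivity-limited
  percolation, soil evaporation, supply-limited transpiration);
* first-order nutrient cycling (mineralization moderated by moisture,
  temperature and an oxygen-depth sigmoid; surface volatilization;
  denitrification near saturation);
* daily stress = min(water, nitrogen, phosphorus, temperature); only the
  single most limiting factor scales the day's biomass gain;
* at maturity, yield = biomass x HI_a with HI_a between hi_max and hi_min
  set by mean water stress over the late season.

The engine is vectorized over grid cells; the scalar entry point
:func:`simulate_season` runs the same code on a single cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .config import (
    ConfigurationError,
    SetupConfig,
    scurve_coefficients,
)
from .errors import DataError, InvariantViolation
from .seeding import derive_rng  # noqa: F401  (re-exported convenience)
from .world import DAYS_PER_YEAR, GridCellEnv, WorldData, _season_indices

__all__ = [
    "SCENARIOS",
    "WATER_REGIMES",
    "SoilState",
    "SeasonResult",
    "heat_units",
    "compute_phu",
    "hargreaves_pet",
    "water_balance_step",
    "nutrient_step",
    "auto_irrigate",
    "auto_fertilize",
    "end_of_year_soil_update",
    "simulate_season",
    "run_ensemble",
]

SCENARIOS = ("default", "fullharm", "harm-suffN")
WATER_REGIMES = ("rainfed", "irrigated")

# process constants (not part of any permuted setup domain)
BASE_MINERALIZATION = 4.0e-4  # 1/d, scaled by the microbial decay coefficient
PLANT_N_FRACTION = 0.015  # kg N per kg potential biomass
PLANT_P_FRACTION = 0.0015  # kg P per kg potential biomass
PAR_FRACTION = 0.5  # photosynthetically active share of shortwave
MAX_INTERCEPTION = 0.85
TRANSPIRATION_SUPPLY_RATE = 0.15  # extractable water accessible per day
CN_BASE = 78.0
CN_SMI_SCALE = 15.0
SAT_DENIT_THRESHOLD = 0.95
RESIDUE_N_RETURN = 0.01  # kg organic N returned per kg aboveground residue


@dataclass
class SoilState:
    """Layered soil state; arrays are (..., n_layers)."""

    thickness: np.ndarray  # m
    field_capacity: np.ndarray  # mm
    wilting_point: np.ndarray  # mm
    ksat: np.ndarray  # mm/d
    storage: np.ndarray  # mm water
    organic_n: np.ndarray  # kg/ha
    mineral_n: np.ndarray  # kg/ha
    labile_p: np.ndarray  # kg/ha

    def copy(self) -> "SoilState":
        return SoilState(**{k: np.array(v, dtype=float) for k, v in vars(self).items()})

    @property
    def n_layers(self) -> int:
        return self.thickness.shape[-1]

    def check(self) -> None:
        if np.any(self.storage < -1e-9):
            raise InvariantViolation("negative soil water storage")
        for name in ("organic_n", "mineral_n", "labile_p"):
            if np.any(getattr(self, name) < -1e-9):
                raise InvariantViolation(f"negative {name} pool")


@dataclass
class SeasonResult:
    """Outcome of one cropping season on one cell."""

    yield_t_ha: float
    aboveground_biomass: float
    hi_actual: float
    stress_days: dict = field(default_factory=dict)
    applied_irrigation: float = 0.0
    applied_n: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations

def heat_units(tmin, tmax, t_base, t_opt):
    """Daily growing-degree accumulation, capped at t_opt - t_base."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise DataError("tmax < tmin")
    mean = (tmin + tmax) / 2.0
    hu = np.clip(mean - t_base, 0.0, np.asarray(t_opt) - np.asarray(t_base))
    return float(hu) if hu.ndim == 0 else hu


def compute_phu(weather_climatology, planting_doy, harvest_doy, t_base, t_opt) -> float:
    """Heat-unit requirement: sum of daily heat units over the mean season.

    ``weather_climatology`` is either a daily-mean temperature array of
    length 360 or a (tmin, tmax) pair of such arrays.  Seasons may wrap the
    year boundary.
    """
    if isinstance(weather_climatology, (tuple, list)):
        tmin, tmax = (np.asarray(a, dtype=float) for a in weather_climatology)
        tmean = (tmin + tmax) / 2.0
    else:
        tmean = np.asarray(weather_climatology, dtype=float)
    if tmean.shape[-1] != DAYS_PER_YEAR:
        raise ConfigurationError("climatology must cover 360 days")
    if not (1 <= planting_doy <= DAYS_PER_YEAR and 1 <= harvest_doy <= DAYS_PER_YEAR):
        raise ConfigurationError("season dates out of range")
    idx = _season_indices(int(planting_doy), int(harvest_doy))
    if len(idx) == 0:
        raise ConfigurationError("season length 0")
    hu = np.clip(tmean[idx - 1] - t_base, 0.0, t_opt - t_base)
    return float(hu.sum())


def extraterrestrial_radiation(lat, doy):
    """Daily extraterrestrial radiation [MJ m-2 d-1], standard solar geometry
    closed form on the 360-day calendar."""
    lat = np.asarray(lat, dtype=float)
    doy = np.asarray(doy, dtype=float)
    ang = 2.0 * np.pi * doy / DAYS_PER_YEAR
    dr = 1.0 + 0.033 * np.cos(ang)
    decl = 0.409 * np.sin(ang - 1.39)
    phi = np.deg2rad(lat)
    x = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def hargreaves_pet(tmin, tmax, lat, doy, lin_coeff=0.0023, exp_coeff=0.5):
    """Hargreaves potential evapotranspiration [mm/d].

    pet = lin * Ra_mm * (Tmean + 17.8) * (Tmax - Tmin)^exp, with Ra
    converted to evaporation-equivalent mm/d (0.408 mm per MJ m-2).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise DataError("tmax < tmin")
    ra_mm = 0.408 * extraterrestrial_radiation(lat, doy)
    tmean = (tmin + tmax) / 2.0
    pet = lin_coeff * ra_mm * np.maximum(tmean + 17.8, 0.0) * (tmax - tmin) ** exp_coeff
    pet = np.maximum(pet, 0.0)
    return float(pet) if pet.ndim == 0 else pet


def water_balance_step(soil: SoilState, precip, irrigation, pet, lai_fraction, coeff_w,
                       _mutate: bool = False):
    """One daily water-balance step.

    Returns (soil', runoff, deep_percolation, actual_et, water_stress).
    Mass balance: d(storage) = precip + irrigation - runoff - actual_et
    - deep_percolation, exactly by construction.  ``water_stress`` is
    actual / potential transpiration in [0, 1] (1 when there is no
    transpiration demand).
    """
    precip = np.asarray(precip, dtype=float)
    irrigation = np.asarray(irrigation, dtype=float)
    pet = np.asarray(pet, dtype=float)
    lai_fraction = np.asarray(lai_fraction, dtype=float)
    new = soil if _mutate else soil.copy()
    st, fc, wp, ks = new.storage, new.field_capacity, new.wilting_point, new.ksat
    L = new.n_layers

    paw = np.sum(np.maximum(st - wp, 0.0), axis=-1)
    cap = np.sum(fc - wp, axis=-1)
    smi = np.clip(paw / cap, 0.0, 1.0)

    # curve-number runoff, CN shifted by the soil-moisture index
    cn = np.clip(CN_BASE + CN_SMI_SCALE * coeff_w.cn_index_coeff * (smi - 0.5), 35.0, 98.0)
    s_ret = 25.4 * (1000.0 / cn - 10.0)
    ia = 0.2 * s_ret
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(precip > ia, (precip - ia) ** 2 / (precip + 0.8 * s_ret), 0.0)
    runoff = np.minimum(q, precip)

    st[..., 0] = st[..., 0] + precip - runoff + irrigation

    # gravity drainage: excess above field capacity, limited by conductivity
    for lyr in range(L):
        excess = np.maximum(st[..., lyr] - fc[..., lyr], 0.0)
        perc = np.minimum(excess, ks[..., lyr])
        st[..., lyr] = st[..., lyr] - perc
        if lyr + 1 < L:
            st[..., lyr + 1] = st[..., lyr + 1] + perc
    deep_perc = perc  # from the bottom layer

    # soil evaporation from the top layer
    es_pot = pet * (1.0 - lai_fraction)
    avail0 = np.maximum(st[..., 0] - wp[..., 0], 0.0)
    cap0 = fc[..., 0] - wp[..., 0]
    rel0 = np.clip(avail0 / cap0, 0.0, 1.0)
    es = np.minimum(es_pot * rel0 ** (2.5 / coeff_w.soil_evap_coeff), avail0)
    st[..., 0] = st[..., 0] - es

    # transpiration limited by a fixed share of plant-available water
    tp = pet * lai_fraction
    extract = np.maximum(st - wp, 0.0)
    supply = TRANSPIRATION_SUPPLY_RATE * np.sum(extract, axis=-1)
    ta = np.minimum(tp, supply)
    tot = np.sum(extract, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot[..., None] > 0, extract / tot[..., None], 0.0)
    st -= frac * ta[..., None]

    with np.errstate(invalid="ignore", divide="ignore"):
        stress = np.where(tp > 0, ta / tp, 1.0)
    water_stress = np.clip(stress, 0.0, 1.0)

    if not _mutate:
        new.check()
    actual_et = es + ta
    if np.ndim(water_stress) == 0:
        return new, float(runoff), float(deep_perc), float(actual_et), float(water_stress)
    return new, runoff, deep_perc, actual_et, water_stress


def _oxygen_factors(soil: SoilState, coeff_n) -> np.ndarray:
    """Per-layer microbial activity multiplier from the oxygen-depth sigmoid."""
    from .config import scurve_from_anchors

    depth_mid = (np.cumsum(soil.thickness, axis=-1) - soil.thickness / 2.0) * 1000.0
    o2_deficit = scurve_from_anchors(
        depth_mid, *coeff_n.oxygen_fn_anchors
    )
    return 1.0 - coeff_n.oxygen_coeff * np.asarray(o2_deficit)


def nutrient_step(
    soil: SoilState,
    temp_factor,
    moisture_factor,
    crop_demand_n,
    crop_demand_p,
    coeff_n,
    oxygen_factor: np.ndarray | None = None,
    return_fluxes: bool = False,
    _mutate: bool = False,
):
    """One daily nutrient-cycling step.

    Mineralization moves organic N to mineral N at a first-order rate
    scaled by the microbial decay coefficient and the moisture, temperature
    and oxygen factors; volatilization removes a fixed fraction of surface
    mineral N per day; denitrification removes mineral N near saturation.
    Supply is capped by the mineral pools; stresses are supply/demand in
    [0, 1] with 1 meaning no limitation.
    """
    temp_factor = np.asarray(temp_factor, dtype=float)
    moisture_factor = np.asarray(moisture_factor, dtype=float)
    demand_n = np.asarray(crop_demand_n, dtype=float)
    demand_p = np.asarray(crop_demand_p, dtype=float)
    new = soil if _mutate else soil.copy()
    if oxygen_factor is None:
        oxygen_factor = _oxygen_factors(new, coeff_n)

    rate = (
        coeff_n.microbial_decay
        * BASE_MINERALIZATION
        * moisture_factor[..., None]
        * temp_factor[..., None]
        * oxygen_factor
    )
    mineralized = np.clip(rate, 0.0, 1.0) * new.organic_n
    new.organic_n = new.organic_n - mineralized
    new.mineral_n = new.mineral_n + mineralized

    vol = coeff_n.n_volatilization * new.mineral_n[..., 0]
    new.mineral_n[..., 0] = new.mineral_n[..., 0] - vol

    wet = moisture_factor > SAT_DENIT_THRESHOLD
    denit = np.where(wet[..., None], coeff_n.denitrification_rate * new.mineral_n, 0.0)
    new.mineral_n = new.mineral_n - denit

    total_n = np.sum(new.mineral_n, axis=-1)
    n_supply = np.minimum(demand_n, total_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_n = np.where(total_n[..., None] > 0, new.mineral_n / total_n[..., None], 0.0)
    new.mineral_n = np.maximum(new.mineral_n - frac_n * n_supply[..., None], 0.0)

    total_p = np.sum(new.labile_p, axis=-1)
    p_supply = np.minimum(demand_p, total_p)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_p = np.where(total_p[..., None] > 0, new.labile_p / total_p[..., None], 0.0)
    new.labile_p = np.maximum(new.labile_p - frac_p * p_supply[..., None], 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_stress = np.where(demand_n > 0, np.minimum(n_supply / demand_n, 1.0), 1.0)
        p_stress = np.where(demand_p > 0, np.minimum(p_supply / demand_p, 1.0), 1.0)

    if not _mutate:
        new.check()
    out = (new, n_supply, p_supply, n_stress, p_stress)
    if return_fluxes:
        fluxes = {
            "mineralized": np.sum(mineralized, axis=-1),
            "volatilized": vol,
            "denitrified": np.sum(denit, axis=-1),
        }
        return out + (fluxes,)
    return out


def auto_irrigate(water_stress, soil_deficit_to_fc, manage):
    """Irrigation applied when water stress falls below the trigger."""
    water_stress = np.asarray(water_stress, dtype=float)
    deficit = np.asarray(soil_deficit_to_fc, dtype=float)
    applied = np.where(
        water_stress < manage.irrigation_trigger,
        np.minimum(deficit, manage.max_single_irrigation),
        0.0,
    )
    return float(applied) if applied.ndim == 0 else applied


def auto_fertilize(n_stress, budget_remaining, manage, scenario):
    """Nitrogen applied when N stress falls below the trigger.

    In ``harm-suffN`` the budget is unbounded; otherwise applications are
    capped by the remaining annual budget.  Fixed-timing management applies
    everything at planting and returns 0 here.
    """
    if manage.fixed_timing and scenario != "harm-suffN":
        return 0.0 if np.ndim(n_stress) == 0 else np.zeros(np.shape(n_stress))
    n_stress = np.asarray(n_stress, dtype=float)
    triggered = n_stress < manage.fert_trigger
    if scenario == "harm-suffN":
        applied = np.where(triggered, manage.fert_dose, 0.0)
    else:
        budget = np.asarray(budget_remaining, dtype=float)
        applied = np.where(triggered, np.minimum(manage.fert_dose, budget), 0.0)
        applied = np.maximum(applied, 0.0)
    return float(applied) if applied.ndim == 0 else applied


def end_of_year_soil_update(soil: SoilState, initial_soil: SoilState, soil_p_block, year_index: int) -> SoilState:
    """Apply the static/dynamic soil handling at a year boundary.

    static: texture and organic pools reset to their initial values; water
    content and mineral N/P carry over.  dynamic: everything carries over
    and ``topsoil_loss_rate`` of the top layer is eroded with proportional
    loss of the layer's stores.  Decadal re-initialization is handled by
    the ensemble driver, not here.
    """
    new = soil.copy()
    if soil_p_block.handling == "static":
        init = initial_soil
        new.thickness = np.array(init.thickness, dtype=float)
        new.field_capacity = np.array(init.field_capacity, dtype=float)
        new.wilting_point = np.array(init.wilting_point, dtype=float)
        new.ksat = np.array(init.ksat, dtype=float)
        new.organic_n = np.array(init.organic_n, dtype=float)
        # storage cannot exceed the re-initialized capacity
        new.storage = np.minimum(new.storage, new.field_capacity)
        return new
    r = soil_p_block.topsoil_loss_rate
    if r > 0.0:
        keep = 1.0 - r
        for name in ("thickness", "field_capacity", "wilting_point", "storage",
                     "organic_n", "mineral_n", "labile_p"):
            arr = getattr(new, name)
            arr[..., 0] = arr[..., 0] * keep
    return new


# ---------------------------------------------------------------------------
# runtime preparation

def _merge_layers(arrs: dict[str, np.ndarray], n_target: int) -> dict[str, np.ndarray]:
    """Merge adjacent soil layers down to ``n_target`` groups.

    Extensive quantities (mm, kg/ha, m) are summed; conductivity takes the
    minimum of the merged members (the limiting layer).
    """
    L = arrs["thickness"].shape[-1]
    if n_target >= L:
        return {k: np.array(v, dtype=float) for k, v in arrs.items()}
    bounds = np.linspace(0, L, n_target + 1).round().astype(int)
    out = {}
    for key, arr in arrs.items():
        pieces = []
        for g in range(n_target):
            sl = arr[..., bounds[g]:bounds[g + 1]]
            pieces.append(np.min(sl, axis=-1) if key == "ksat" else np.sum(sl, axis=-1))
        out[key] = np.stack(pieces, axis=-1)
    return out


def _initial_soil(env: dict, config: SetupConfig) -> SoilState:
    """Initial soil state after applying the soil-data domain."""
    fc = np.array(env["field_capacity"], dtype=float)
    wp = np.array(env["wilting_point"], dtype=float)
    ks = np.array(env["ksat"], dtype=float)
    if config.soil_d.hydraulic_source == "online_pedotransfer_B":
        # alternative pedotransfer: lower FC, higher WP, faster drainage
        fc_b = 0.92 * fc
        wp_b = np.minimum(1.12 * wp, 0.9 * fc_b)
        fc, wp, ks = fc_b, wp_b, 1.4 * ks
    arrs = {
        "thickness": env["layer_thickness"],
        "field_capacity": fc,
        "wilting_point": wp,
        "ksat": ks,
        "organic_n": env["organic_n"],
        "mineral_n": env["mineral_n"],
        "labile_p": env["labile_p"],
    }
    arrs = _merge_layers(arrs, config.soil_d.n_layers)
    storage = arrs["wilting_point"] + 0.75 * (arrs["field_capacity"] - arrs["wilting_point"])
    return SoilState(storage=storage, **arrs)


def _cell_env(world: WorldData) -> dict:
    return {
        "n_cells": world.n_cells,
        "n_years": world.n_years,
        "lat": world.lat,
        "tmin": world.tmin,
        "tmax": world.tmax,
        "srad": world.srad,
        "precip": world.precip,
        "layer_thickness": world.layer_thickness,
        "field_capacity": world.field_capacity,
        "wilting_point": world.wilting_point,
        "ksat": world.ksat,
        "organic_n": world.organic_n,
        "mineral_n": world.mineral_n,
        "labile_p": world.labile_p,
        "n_rate": world.n_rate,
        "p_rate": world.p_rate,
        "planting_doy": world.planting_doy,
        "harvest_doy": world.harvest_doy,
        "climate_region": world.climate_region,
        "country_dev_cell": np.array(
            [world.country_dev[int(c)] for c in world.country_id]
        ),
    }


def _single_cell_env(cell: GridCellEnv, country_dev: float) -> dict:
    n_days = len(cell.tmin)
    return {
        "n_cells": 1,
        "n_years": n_days // DAYS_PER_YEAR,
        "lat": np.array([cell.lat]),
        "tmin": cell.tmin[None, :],
        "tmax": cell.tmax[None, :],
        "srad": cell.srad[None, :],
        "precip": cell.precip[None, :],
        "layer_thickness": cell.layer_thickness[None, :],
        "field_capacity": cell.field_capacity[None, :],
        "wilting_point": cell.wilting_point[None, :],
        "ksat": cell.ksat[None, :],
        "organic_n": cell.organic_n[None, :],
        "mineral_n": cell.mineral_n[None, :],
        "labile_p": cell.labile_p[None, :],
        "n_rate": np.array([cell.n_rate]),
        "p_rate": np.array([cell.p_rate]),
        "planting_doy": np.array([cell.planting_doy]),
        "harvest_doy": np.array([cell.harvest_doy]),
        "climate_region": np.array([cell.climate_region]),
        "country_dev_cell": np.array([country_dev]),
    }


class _Runtime:
    """Per (config, scenario, water) precomputed arrays and parameters."""

    def __init__(self, env: dict, config: SetupConfig, scenario: str, water: str,
                 disable_p_stress: bool = False):
        if scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {scenario!r}")
        if water not in WATER_REGIMES:
            raise ConfigurationError(f"unknown water regime {water!r}")
        self.config = config
        self.scenario = scenario
        self.water = water
        self.disable_p_stress = disable_p_stress or scenario == "harm-suffN"
        self.suff_nutrients = scenario == "harm-suffN"
        n = env["n_cells"]
        n_days = env["n_years"] * DAYS_PER_YEAR

        # cultivar assignment and parameter vectors
        cult = config.cult
        ids = np.array(
            [
                cult.cultivar_for_cell(str(env["climate_region"][i]),
                                       float(env["country_dev_cell"][i]))
                for i in range(n)
            ]
        )
        pars = cult.cultivars
        self.cultivar_id = ids
        self.hi_min = np.array([pars[i].hi_min for i in ids])
        self.hi_max = np.array([pars[i].hi_max for i in ids])
        self.t_base = np.array([pars[i].t_base for i in ids])
        self.t_opt = np.array([pars[i].t_opt for i in ids])
        self.rue = np.array([pars[i].rue for i in ids])
        self.f_hi = cult.hi_sensitive_fraction

        # scenario-dependent season dates and fertilizer budget
        shift = config.manage.default_season_shift if scenario == "default" else 0
        self.plant_doy = (env["planting_doy"] - 1 + shift) % DAYS_PER_YEAR + 1
        self.harvest_doy = (env["harvest_doy"] - 1 + shift) % DAYS_PER_YEAR + 1
        if scenario == "default":
            self.annual_n = env["n_rate"] * config.manage.default_n_scale
        else:
            self.annual_n = np.array(env["n_rate"], dtype=float)
        self.p_rate = np.array(env["p_rate"], dtype=float)

        # PHU from the per-cell mean climatology for this config's cultivar
        tmean = (env["tmin"] + env["tmax"]) / 2.0
        clim = tmean.reshape(n, env["n_years"], DAYS_PER_YEAR).mean(axis=1)
        self.phu = np.empty(n)
        for i in range(n):
            self.phu[i] = max(
                compute_phu(clim[i], int(self.plant_doy[i]), int(self.harvest_doy[i]),
                            self.t_base[i], self.t_opt[i]),
                1.0,
            )

        # precomputed daily tables (cells x days)
        doy = np.arange(n_days) % DAYS_PER_YEAR + 1.0
        self.pet = hargreaves_pet(
            env["tmin"], env["tmax"], env["lat"][:, None], doy[None, :],
            config.coeff_w.hargreaves_lin, config.coeff_w.hargreaves_exp,
        )
        self.hu_table = np.clip(
            tmean - self.t_base[:, None], 0.0, (self.t_opt - self.t_base)[:, None]
        )
        # generous ramp: no temperature limitation from halfway to optimum
        self.ts_table = np.clip(
            2.0 * (tmean - self.t_base[:, None]) / (self.t_opt - self.t_base)[:, None],
            0.0, 1.0,
        )
        self.temp_factor_table = np.clip(tmean / 35.0, 0.0, 1.0)
        self.moisture_b = scurve_coefficients(*config.coeff_n.moisture_fn_anchors)

        self.soil_init = _initial_soil(env, config)
        self.oxygen_factor = _oxygen_factors(self.soil_init, config.coeff_n)
        self.fert_layer = min(1, self.soil_init.n_layers - 1)


class _CropState:
    def __init__(self, n: int):
        self.growing = np.zeros(n, dtype=bool)
        self.hu = np.zeros(n)
        self.biomass = np.zeros(n)
        self.wsi_sum = np.zeros(n)
        self.wsi_n = np.zeros(n)
        self.budget = np.zeros(n)
        self.applied_irr = np.zeros(n)
        self.applied_n = np.zeros(n)
        self.prev_ws = np.ones(n)
        self.prev_ns = np.ones(n)
        self.stress_days = np.zeros((4, n))  # water, nitrogen, phosphorus, temperature


def _moisture_index(soil: SoilState) -> np.ndarray:
    paw = np.sum(np.maximum(soil.storage - soil.wilting_point, 0.0), axis=-1)
    cap = np.sum(soil.field_capacity - soil.wilting_point, axis=-1)
    return np.clip(paw / cap, 0.0, 1.0)


def _scurve_eval(x: np.ndarray, b: tuple[float, float]) -> np.ndarray:
    b1, b2 = b
    xp = np.maximum(x, 1e-12)
    return np.where(x <= 0, 0.0, xp / (xp + np.exp(b1 - b2 * xp)))


def _simulate_days(
    env: dict,
    rt: _Runtime,
    soil: SoilState,
    crop: _CropState,
    day_index: np.ndarray,
    record: np.ndarray | None,
    year_of_day: np.ndarray | None,
    collect: dict | None = None,
):
    """Run the daily loop over ``day_index`` (absolute day indices).

    ``record`` is a (n_years, n_cells) array receiving yields at harvest
    (indexed by ``year_of_day``), or None to discard (spin-up).
    """
    cfg = rt.config
    manage = cfg.manage
    irrigated = rt.water == "irrigated"
    soil_init = rt.soil_init
    n = env["n_cells"]

    for k, d in enumerate(day_index):
        doy = d % DAYS_PER_YEAR + 1

        # planting
        plant = (doy == rt.plant_doy) & ~crop.growing
        if plant.any():
            crop.growing |= plant
            for arr in (crop.hu, crop.biomass, crop.wsi_sum, crop.wsi_n,
                        crop.applied_irr, crop.applied_n):
                arr[plant] = 0.0
            crop.budget[plant] = rt.annual_n[plant]
            crop.prev_ws[plant] = 1.0
            crop.prev_ns[plant] = 1.0
            crop.stress_days[:, plant] = 0.0
            soil.labile_p[..., 0] = soil.labile_p[..., 0] + np.where(plant, rt.p_rate, 0.0)
            if manage.fixed_timing and not rt.suff_nutrients:
                dose = np.where(plant, crop.budget, 0.0)
                soil.mineral_n[..., rt.fert_layer] += dose
                crop.applied_n += dose
                crop.budget = np.where(plant, 0.0, crop.budget)

        hui = np.clip(crop.hu / rt.phu, 0.0, 1.0)
        lai_frac = np.where(
            crop.growing,
            MAX_INTERCEPTION / (1.0 + np.exp(-8.0 * (hui - 0.35))),
            0.0,
        )

        # irrigation decided on yesterday's stress
        irr = 0.0
        if irrigated:
            deficit = np.sum(np.maximum(soil.field_capacity - soil.storage, 0.0), axis=-1)
            irr = auto_irrigate(crop.prev_ws, deficit, manage) * crop.growing

        soil, runoff, perc, aet, ws = water_balance_step(
            soil, env["precip"][:, d], irr, rt.pet[:, d], lai_frac, cfg.coeff_w,
            _mutate=True,
        )
        crop.applied_irr += np.asarray(irr) * crop.growing

        # potential growth and nutrient demand
        dbp = rt.rue * manage.row_spacing_factor * PAR_FRACTION * lai_frac \
            * env["srad"][:, d] * 0.01  # t/ha
        demand_n = np.where(crop.growing, PLANT_N_FRACTION * dbp * 1000.0, 0.0)
        demand_p = np.where(crop.growing, PLANT_P_FRACTION * dbp * 1000.0, 0.0)

        # fertilization decided on yesterday's N stress
        if not manage.fixed_timing and not rt.suff_nutrients:
            fert = auto_fertilize(crop.prev_ns, crop.budget, manage, rt.scenario)
            fert = np.asarray(fert) * crop.growing
            soil.mineral_n[..., rt.fert_layer] += fert
            crop.budget = np.maximum(crop.budget - fert, 0.0)
            crop.applied_n += fert

        smi = _moisture_index(soil)
        moisture_factor = _scurve_eval(smi, rt.moisture_b)
        soil, n_sup, p_sup, ns, ps = nutrient_step(
            soil,
            rt.temp_factor_table[:, d],
            moisture_factor,
            demand_n,
            demand_p,
            cfg.coeff_n,
            oxygen_factor=rt.oxygen_factor,
            _mutate=True,
        )
        if rt.suff_nutrients:
            ns = np.ones(n)
            ps = np.ones(n)
        elif rt.disable_p_stress:
            ps = np.ones(n)

        ts = rt.ts_table[:, d]
        stresses = np.stack([ws, ns, ps, ts])
        s_min = stresses.min(axis=0)
        binding = stresses.argmin(axis=0)
        limited = crop.growing & (s_min < 1.0)
        for j in range(4):
            crop.stress_days[j] += limited & (binding == j)

        crop.biomass += np.where(crop.growing, dbp * s_min, 0.0)
        crop.hu += np.where(crop.growing, rt.hu_table[:, d], 0.0)

        late = crop.growing & (hui >= rt.f_hi)
        crop.wsi_sum += np.where(late, 1.0 - ws, 0.0)
        crop.wsi_n += late

        crop.prev_ws = np.asarray(ws, dtype=float)
        crop.prev_ns = np.asarray(ns, dtype=float)

        # maturity / forced harvest
        mature = crop.growing & ((crop.hu >= rt.phu) | (doy == rt.harvest_doy))
        if mature.any():
            wsi = np.clip(crop.wsi_sum / np.maximum(crop.wsi_n, 1.0), 0.0, 1.0)
            hi_a = rt.hi_max - (rt.hi_max - rt.hi_min) * wsi
            yld = crop.biomass * hi_a
            if record is not None:
                yr = year_of_day[k]
                record[yr, mature] = yld[mature]
            # crop residues replenish the topsoil organic pool
            residue = (
                RESIDUE_N_RETURN * 1000.0 * crop.biomass
                * (1.0 - manage.residue_removal)
            )
            soil.organic_n[..., 0] = soil.organic_n[..., 0] + np.where(
                mature, residue, 0.0
            )
            if collect is not None and mature[collect["cell"]]:
                i = collect["cell"]
                collect["result"] = SeasonResult(
                    yield_t_ha=float(yld[i]),
                    aboveground_biomass=float(crop.biomass[i]),
                    hi_actual=float(hi_a[i]),
                    stress_days={
                        "water": int(crop.stress_days[0, i]),
                        "nitrogen": int(crop.stress_days[1, i]),
                        "phosphorus": int(crop.stress_days[2, i]),
                        "temperature": int(crop.stress_days[3, i]),
                    },
                    applied_irrigation=float(crop.applied_irr[i]),
                    applied_n=float(crop.applied_n[i]),
                )
            crop.growing &= ~mature

        if doy == DAYS_PER_YEAR:
            soil.check()
            soil = end_of_year_soil_update(soil, soil_init, cfg.soil_p, d // DAYS_PER_YEAR)

        if collect is not None and collect.get("result") is not None:
            return soil
    return soil


def _run_one(env: dict, config: SetupConfig, scenario: str, water: str,
             disable_p_stress: bool = False) -> np.ndarray:
    """Simulate all years for one (config, scenario, water); returns
    (n_years, n_cells) yields with year 1 set to NaN."""
    rt = _Runtime(env, config, scenario, water, disable_p_stress)
    n_years = env["n_years"]
    n = env["n_cells"]
    record = np.full((n_years, n), np.nan)

    if config.soil_p.continuity == "decadal":
        decades = [
            (start, min(start + 10, n_years))
            for start in range(0, n_years, 10)
        ]
        for start, stop in decades:
            soil = rt.soil_init.copy()
            crop = _CropState(n)
            if config.soil_p.spinup_years > 0:
                # spin up on the decade's first year of weather, unscored
                first_year_days = np.arange(start * DAYS_PER_YEAR, (start + 1) * DAYS_PER_YEAR)
                spin_days = np.tile(first_year_days, config.soil_p.spinup_years)
                soil = _simulate_days(env, rt, soil, crop, spin_days, None, None)
            days = np.arange(start * DAYS_PER_YEAR, stop * DAYS_PER_YEAR)
            years = days // DAYS_PER_YEAR
            _simulate_days(env, rt, soil, crop, days, record, years)
    else:
        soil = rt.soil_init.copy()
        crop = _CropState(n)
        days = np.arange(0, n_years * DAYS_PER_YEAR)
        years = days // DAYS_PER_YEAR
        _simulate_days(env, rt, soil, crop, days, record, years)

    return record


def _config_fingerprint(config: SetupConfig) -> str:
    """Stable content key for a config, ignoring its label."""
    import dataclasses

    d = dataclasses.asdict(config)
    d.pop("label", None)
    return repr(sorted(d.items()))


def simulate_season(
    cell: GridCellEnv,
    config: SetupConfig,
    scenario: str = "fullharm",
    water_regime: str = "rainfed",
    carryover_state: SoilState | None = None,
    country_dev: float = 0.5,
) -> tuple[SeasonResult, SoilState]:
    """Simulate the first complete cropping season on one cell.

    Returns the season outcome and the soil state at harvest (usable as
    carry-over for a subsequent season).
    """
    env = _single_cell_env(cell, country_dev)
    rt = _Runtime(env, config, scenario, water_regime)
    soil = carryover_state.copy() if carryover_state is not None else rt.soil_init.copy()
    crop = _CropState(1)
    n_days = env["n_years"] * DAYS_PER_YEAR
    collect = {"cell": 0, "result": None}
    days = np.arange(n_days)
    record = np.full((env["n_years"], 1), np.nan)
    soil = _simulate_days(env, rt, soil, crop, days, record, days // DAYS_PER_YEAR,
                          collect=collect)
    if collect["result"] is None:
        raise DataError("no complete season within the supplied weather")
    return collect["result"], soil


def run_ensemble(
    world: WorldData,
    configs: list[SetupConfig],
    scenarios=SCENARIOS,
    water_regimes=WATER_REGIMES,
    disable_p_stress: bool = False,
) -> xr.DataArray:
    """Run the full ensemble and return the yield cube.

    Dimensions: (config, scenario, water, year, cell); units t/ha.  Year 1
    is flagged incomplete (NaN).  Deterministic for a fixed world.
    """
    if len(configs) < 1:
        raise ConfigurationError("need at least one config")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("config labels must be unique")
    for s in scenarios:
        if s not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {s!r}")
    env = _cell_env(world)
    data = np.full(
        (len(configs), len(scenarios), len(water_regimes), world.n_years, world.n_cells),
        np.nan,
    )
    # configs with identical parameter content behave identically (splicing
    # is exact), so duplicate runs are shared
    cache: dict[str, np.ndarray] = {}
    for ic, config in enumerate(configs):
        key_cfg = _config_fingerprint(config)
        for isc, scenario in enumerate(scenarios):
            for iw, water in enumerate(water_regimes):
                key = f"{key_cfg}|{scenario}|{water}"
                if key not in cache:
                    cache[key] = _run_one(env, config, scenario, water,
                                          disable_p_stress)
                data[ic, isc, iw] = cache[key]
    cube = xr.DataArray(
        data,
        dims=("config", "scenario", "water", "year", "cell"),
        coords={
            "config": labels,
            "scenario": list(scenarios),
            "water": list(water_regimes),
            "year": world.years,
            "cell": np.arange(world.n_cells),
            # year 1 has no complete growing season and is excluded from
            # downstream means
            "year_valid": ("year", world.years > 1),
        },
        name="yield",
        attrs={"units": "t ha-1", "first_valid_year": 2},
    )
    return cube
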