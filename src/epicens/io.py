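"""Standard-format I/O: yield cubes, worlds, manifests.

Cubes travel as NetCDF (scipy backend, classic format) with named
dimensions (config, scenario, water, year, cell) and a mandatory
``units = "t ha-1"`` attribute, or as long-format CSV with the same fields.
Worlds are written as NetCDF plus a CSV country table and a JSON record of
the generator parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError
from .world import DAYS_PER_YEAR, WorldData

__all__ = [
    "write_yield_cube",
    "read_yield_cube",
    "cube_to_csv",
    "cube_from_csv",
    "write_world",
    "read_world",
    "write_manifest",
    "sha256_file",
]

CUBE_DIMS = ("config", "scenario", "water", "year", "cell")
CUBE_UNITS = "t ha-1"


def _check_cube(cube: xr.DataArray) -> None:
    for d in CUBE_DIMS:
        if d not in cube.dims:
            raise FormatError(f"yield cube missing dimension {d!r}")
    if cube.attrs.get("units") != CUBE_UNITS:
        raise FormatError(f'yield cube must carry units attribute "{CUBE_UNITS}"')


def _nc3_safe(ds: xr.Dataset) -> xr.Dataset:
    # classic NetCDF has no int64/bool
    for name in list(ds.coords) + list(ds.data_vars):
        v = ds[name]
        if v.dtype == np.int64:
            ds[name] = v.astype("i4")
        elif v.dtype == bool:
            ds[name] = v.astype("i1")
    return ds


def write_yield_cube(cube: xr.DataArray, path) -> None:
    _check_cube(cube)
    ds = _nc3_safe(cube.transpose(*CUBE_DIMS).to_dataset(name="yield"))
    ds.to_netcdf(path, engine="scipy")


def read_yield_cube(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    if "yield" not in ds:
        raise FormatError('no "yield" variable in cube file')
    cube = ds["yield"].load()
    ds.close()
    for coord in ("config", "scenario", "water"):
        cube = cube.assign_coords({coord: cube[coord].values.astype("U")})
    for coord in ("year", "cell"):
        cube = cube.assign_coords({coord: cube[coord].values.astype(np.int64)})
    if "year_valid" in cube.coords:
        cube = cube.assign_coords(year_valid=("year", cube["year_valid"].values.astype(bool)))
    _check_cube(cube)
    return cube


def cube_to_csv(cube: xr.DataArray, path) -> None:
    _check_cube(cube)
    df = cube.transpose(*CUBE_DIMS).to_dataframe().reset_index()
    df.to_csv(path, index=False)


def cube_from_csv(path) -> xr.DataArray:
    df = pd.read_csv(path)
    missing = [c for c in CUBE_DIMS + ("yield",) if c not in df.columns]
    if missing:
        raise FormatError(f"cube CSV missing columns {missing}")
    da = df.set_index(list(CUBE_DIMS))["yield"].to_xarray()
    da.name = "yield"
    da.attrs["units"] = CUBE_UNITS
    return da


# ---------------------------------------------------------------------------
# world serialization

def write_world(world: WorldData, directory) -> dict[str, Path]:
    """Write a world as NetCDF + country CSV + generator-parameter JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": directory / "world.nc",
        "countries": directory / "countries.csv",
        "params": directory / "world_params.json",
    }
    day = np.arange(world.n_days)
    layer = np.arange(world.layer_thickness.shape[1])
    cell = np.arange(world.n_cells)
    ds = xr.Dataset(
        {
            "tmin": (("cell", "day"), world.tmin, {"units": "degC"}),
            "tmax": (("cell", "day"), world.tmax, {"units": "degC"}),
            "srad": (("cell", "day"), world.srad, {"units": "MJ m-2 d-1"}),
            "precip": (("cell", "day"), world.precip, {"units": "mm d-1"}),
            "layer_thickness": (("cell", "layer"), world.layer_thickness, {"units": "m"}),
            "field_capacity": (("cell", "layer"), world.field_capacity, {"units": "mm"}),
            "wilting_point": (("cell", "layer"), world.wilting_point, {"units": "mm"}),
            "ksat": (("cell", "layer"), world.ksat, {"units": "mm d-1"}),
            "organic_n": (("cell", "layer"), world.organic_n, {"units": "kg ha-1"}),
            "mineral_n": (("cell", "layer"), world.mineral_n, {"units": "kg ha-1"}),
            "labile_p": (("cell", "layer"), world.labile_p, {"units": "kg ha-1"}),
            "lat": (("cell",), world.lat),
            "country_id": (("cell",), world.country_id.astype("i4")),
            "mean_annual_precip": (("cell",), world.mean_annual_precip),
            "n_rate": (("cell",), world.n_rate),
            "p_rate": (("cell",), world.p_rate),
            "area_rainfed": (("cell",), world.area_rainfed),
            "area_irrigated": (("cell",), world.area_irrigated),
            "planting_doy": (("cell",), world.planting_doy.astype("i4")),
            "harvest_doy": (("cell",), world.harvest_doy.astype("i4")),
            "phu": (("cell",), world.phu),
        },
        coords={"cell": cell, "day": day, "layer": layer},
        # seed as string: classic-format attributes cannot hold 64-bit ints
        attrs={"n_years": world.n_years, "seed": str(world.seed),
               "days_per_year": DAYS_PER_YEAR},
    )
    _nc3_safe(ds).to_netcdf(paths["grid"], engine="scipy")

    regions = pd.DataFrame(
        {
            "country_id": sorted(world.countries),
            "name": [world.countries[k] for k in sorted(world.countries)],
            "development": [world.country_dev[k] for k in sorted(world.countries)],
        }
    )
    regions.to_csv(paths["countries"], index=False)
    # climate regions ride along in the params file (strings are awkward in
    # classic NetCDF)
    record = dict(world.generator_params)
    record["climate_region"] = [str(r) for r in world.climate_region]
    with open(paths["params"], "w") as fh:
        json.dump(record, fh, indent=1)
    return paths


def read_world(directory) -> WorldData:
    directory = Path(directory)
    ds = xr.open_dataset(directory / "world.nc", engine="scipy").load()
    countries = pd.read_csv(directory / "countries.csv")
    with open(directory / "world_params.json") as fh:
        params = json.load(fh)
    region = np.array(params.pop("climate_region"), dtype="U9")
    world = WorldData(
        n_cells=ds.sizes["cell"],
        n_years=int(ds.attrs["n_years"]),
        seed=int(ds.attrs["seed"]),
        lat=ds["lat"].values,
        country_id=ds["country_id"].values.astype(np.int64),
        climate_region=region,
        mean_annual_precip=ds["mean_annual_precip"].values,
        tmin=ds["tmin"].values,
        tmax=ds["tmax"].values,
        srad=ds["srad"].values,
        precip=ds["precip"].values,
        layer_thickness=ds["layer_thickness"].values,
        field_capacity=ds["field_capacity"].values,
        wilting_point=ds["wilting_point"].values,
        ksat=ds["ksat"].values,
        organic_n=ds["organic_n"].values,
        mineral_n=ds["mineral_n"].values,
        labile_p=ds["labile_p"].values,
        n_rate=ds["n_rate"].values,
        p_rate=ds["p_rate"].values,
        area_rainfed=ds["area_rainfed"].values,
        area_irrigated=ds["area_irrigated"].values,
        planting_doy=ds["planting_doy"].values.astype(np.int64),
        harvest_doy=ds["harvest_doy"].values.astype(np.int64),
        phu=ds["phu"].values,
        countries=dict(zip(countries["country_id"].astype(int), countries["name"])),
        country_dev=dict(
            zip(countries["country_id"].astype(int), countries["development"])
        ),
        generator_params=params,
    )
    ds.close()
    world.validate()
    return world


# ---------------------------------------------------------------------------
# run manifests

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, seed: int, scenarios, outputs, version: str,
                   config_labels=(), timestamp: str = "") -> None:
    """JSON run manifest listing every output file with its checksum."""
    manifest = {
        "version": version,
        "seed": seed,
        "scenarios": list(scenarios),
        "configs": list(config_labels),
        "timestamp": timestamp,
        "outputs": {
            str(p): sha256_file(p) for p in outputs
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
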