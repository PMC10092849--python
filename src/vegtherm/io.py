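"""Scene and result I/O.

Scenes travel as CF-style NetCDF (classic format via the scipy backend)
with explicit unit attributes; planted truth as JSON; configurations as
YAML; tabular summaries as CSV.  Reads validate variable presence, grid
alignment and units and fail with the offending name rather than guessing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .domain import FIELD_UNITS, FieldStack, GridDomain
from .diurnal import DiurnalCube
from .synthetic import AnnualPanel, Scene, SceneConfig, TruthBundle

__all__ = ["write_scene", "read_scene", "write_outputs"]

_SCENE_VARS = ("lst", "qc") + tuple(FIELD_UNITS) + ("ndvi_annual", "lst_annual",
                                                    "p_annual", "rs_annual")


def scene_to_dataset(scene: Scene) -> xr.Dataset:
    f = scene.fields
    ds = xr.Dataset(
        {
            "lst": (("pixel", "day", "time_of_day"), scene.cube.lst,
                    {"units": "K"}),
            "qc": (("pixel", "day", "time_of_day"),
                   scene.cube.qc.astype("i1"), {"flag_meanings": "invalid valid"}),
            "ndvi_annual": (("pixel", "year"), scene.panel.ndvi, {"units": "1"}),
            "lst_annual": (("pixel", "year"), scene.panel.lst, {"units": "K"}),
            "p_annual": (("pixel", "year"), scene.panel.p, {"units": "mm yr-1"}),
            "rs_annual": (("pixel", "year"), scene.panel.rs, {"units": "W m-2"}),
        },
        coords={
            "pixel": np.arange(scene.domain.n_pixels),
            "time_of_day": ("time_of_day", scene.cube.times, {"units": "hours"}),
            "year": scene.panel.years,
            "lat": ("pixel", scene.domain.lat, {"units": "degrees_north"}),
            "lon": ("pixel", scene.domain.lon, {"units": "degrees_east"}),
        },
        attrs={"cell_size": scene.domain.cell_size, "Conventions": "CF-1.8"},
    )
    for name, units in FIELD_UNITS.items():
        arr = getattr(f, name)
        if name == "landcover":
            ds[name] = ("pixel", arr.astype("i4"),
                        {"units": units, "flag_meanings": "IGBP codes 1-17"})
        else:
            ds[name] = ("pixel", np.asarray(arr, dtype=float), {"units": units})
    return ds


def write_scene(scene: Scene, out_dir) -> Path:
    """Write scene.nc + truth.json (+ config.json) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = scene_to_dataset(scene)
    ds.to_netcdf(out / "scene.nc", engine="scipy")
    truth = scene.truth
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "beta_fvc_true": truth.beta_fvc_true.tolist(),
                "beta_albedo_true": truth.beta_albedo_true.tolist(),
                "beta_ndvi_true": truth.beta_ndvi_true.tolist(),
                "beta_p_true": truth.beta_p_true,
                "beta_rs_true": truth.beta_rs_true,
                "effect_class_true": truth.effect_class_true.tolist(),
                "r0": truth.r0.tolist(),
            },
            fh,
        )
    return out / "scene.nc"


def read_scene(path) -> Tuple[GridDomain, FieldStack, DiurnalCube, AnnualPanel]:
    """Read a scene.nc; validates variables, units and alignment."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    missing = [v for v in _SCENE_VARS if v not in ds]
    if missing:
        raise ValueError(f"scene file missing variable(s): {missing}")
    if ds.sizes.get("pixel", 0) == 0:
        raise ValueError("empty domain")
    for name, units in FIELD_UNITS.items():
        got = ds[name].attrs.get("units")
        if got is None:
            raise ValueError(f"variable {name} lacks a units attribute")
        if got != units:
            raise ValueError(f"unit mismatch for {name}: {got!r} != {units!r}")
    if ds["lst"].attrs.get("units") != "K":
        raise ValueError("lst units attribute must be 'K'")
    n = ds.sizes["pixel"]
    for v in _SCENE_VARS:
        if ds[v].sizes.get("pixel") != n:
            raise ValueError(f"variable {v} misaligned with the grid")
    domain = GridDomain(lat=ds["lat"].values, lon=ds["lon"].values,
                        cell_size=float(ds.attrs.get("cell_size", np.nan)))
    fields = FieldStack(**{name: ds[name].values for name in FIELD_UNITS})
    cube = DiurnalCube(lst=ds["lst"].values, qc=ds["qc"].values.astype(bool),
                       times=ds["time_of_day"].values, lon=ds["lon"].values)
    panel = AnnualPanel(ndvi=ds["ndvi_annual"].values, lst=ds["lst_annual"].values,
                        p=ds["p_annual"].values, rs=ds["rs_annual"].values,
                        years=ds["year"].values)
    return domain, fields, cube, panel


def read_truth(path) -> TruthBundle:
    with open(path) as fh:
        raw = json.load(fh)
    return TruthBundle(
        beta_fvc_true=np.asarray(raw["beta_fvc_true"]),
        beta_albedo_true=np.asarray(raw["beta_albedo_true"]),
        beta_ndvi_true=np.asarray(raw["beta_ndvi_true"]),
        beta_p_true=raw["beta_p_true"], beta_rs_true=raw["beta_rs_true"],
        effect_class_true=np.asarray(raw["effect_class_true"]),
        r0=np.asarray(raw["r0"]),
    )


def write_outputs(results: dict, out_dir) -> None:
    """Write analysis outputs: DataFrames as CSV, arrays as NetCDF layers,
    plain mappings as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
        elif isinstance(obj, np.ndarray):
            arrays[name] = ("pixel", np.asarray(obj, dtype=float))
        else:
            with open(out / f"{name}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=float)
    if arrays:
        xr.Dataset(arrays).to_netcdf(out / "maps.nc", engine="scipy")
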