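"""File round-trips: forcing readers/writers, output tables, run manifests.

Two on-disk forcing dialects carry the same information:

* CSV — one row per step, ``time`` column plus the documented per-layer
  columns (``tsoil_k_l1``...); readable anywhere.
* netCDF — dimensions ``(time, layer)`` with CF-style ``units``
  attributes, written through xarray (NETCDF3 via the scipy engine).

Both round-trip bit-exactly through :class:`~soildoc.forcing.ForcingSeries`.
Simulation outputs go to a tidy per-step CSV and an aggregated netCDF
with ``(time, layer, pool)``/``(time, class, layer)`` dimensions; every
run directory also receives a plain-text manifest (config echo, seed,
package version) so results are attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .column import SimulationResult
from .errors import ForcingError
from .forcing import ForcingSeries
from .soil_carbon import POOL_NAMES
from .doc_dynamics import DOC_CLASSES

__all__ = [
    "read_forcing",
    "write_forcing",
    "write_outputs",
    "write_manifest",
    "NETCDF_UNITS",
]

#: netCDF variable names and mandatory units attributes.
NETCDF_UNITS = {
    "soil_temperature": "K",
    "soil_water": "kg m-2",
    "saturation_fraction": "1",
    "surface_runoff": "kg m-2 step-1",
    "subsurface_runoff": "kg m-2 step-1",
    "drainage": "kg m-2 step-1",
    "litter_input": "g C m-2 step-1",
    "vegetation_cover": "1",
    "npp": "g C m-2 yr-1",
}

_LAYERED = {"soil_temperature", "soil_water", "saturation_fraction"}


def _forcing_to_dataset(forcing: ForcingSeries) -> xr.Dataset:
    coords = {"time": forcing.times, "layer": np.arange(1, forcing.n_layers + 1)}
    data = {
        "soil_temperature": (("time", "layer"), forcing.t_soil),
        "soil_water": (("time", "layer"), forcing.water),
        "saturation_fraction": (("time", "layer"), forcing.sat_frac),
        "surface_runoff": (("time",), forcing.surf_runoff),
        "subsurface_runoff": (("time",), forcing.sub_runoff),
        "drainage": (("time",), forcing.drainage),
        "litter_input": (("time",), forcing.litter),
        "vegetation_cover": (("time",), forcing.veg_cover),
    }
    if forcing.npp is not None:
        data["npp"] = (("time",), forcing.npp)
    ds = xr.Dataset(data, coords=coords)
    for name, units in NETCDF_UNITS.items():
        if name in ds:
            ds[name].attrs["units"] = units
    ds.attrs["dt_seconds"] = forcing.dt
    return ds


def write_forcing(forcing: ForcingSeries, path: str | Path, format: str | None = None) -> Path:
    """Write a forcing series as CSV or netCDF (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "csv":
        forcing.to_dataframe().to_csv(path, index_label="time")
    elif fmt == "netcdf":
        _forcing_to_dataset(forcing).to_netcdf(path, engine="scipy")
    else:
        raise ForcingError(f"unknown forcing format {fmt!r} (csv or netcdf)")
    return path


def _dataset_to_forcing(ds: xr.Dataset) -> ForcingSeries:
    for name in NETCDF_UNITS:
        if name == "npp":
            continue
        if name not in ds:
            raise ForcingError(f"missing forcing variable {name!r}")
        units = ds[name].attrs.get("units")
        if units is not None and units != NETCDF_UNITS[name]:
            raise ForcingError(
                f"variable {name!r} has units {units!r}, expected {NETCDF_UNITS[name]!r}")
    times = pd.DatetimeIndex(ds["time"].values)
    if len(times) < 2:
        raise ForcingError("forcing needs at least two steps to define dt")
    deltas = np.diff(times.values).astype("timedelta64[s]").astype(float)
    gaps = np.flatnonzero(deltas != deltas[0])
    if gaps.size:
        intervals = [f"{times[g]} -> {times[g + 1]}" for g in gaps[:5]]
        raise ForcingError(f"forcing has time gaps at: {', '.join(intervals)}")
    return ForcingSeries(
        start=np.datetime64(times[0].to_datetime64(), "s"),
        dt=float(deltas[0]),
        t_soil=ds["soil_temperature"].values,
        water=ds["soil_water"].values,
        sat_frac=ds["saturation_fraction"].values,
        surf_runoff=ds["surface_runoff"].values,
        sub_runoff=ds["subsurface_runoff"].values,
        drainage=ds["drainage"].values,
        litter=ds["litter_input"].values,
        veg_cover=ds["vegetation_cover"].values,
        npp=ds["npp"].values if "npp" in ds else None,
    )


def read_forcing(path: str | Path, format: str | None = None) -> ForcingSeries:
    """Read a forcing series; validates schema, units and gap-freeness."""
    path = Path(path)
    fmt = format or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, parse_dates=["time"]).set_index("time")
        return ForcingSeries.from_dataframe(df)
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            return _dataset_to_forcing(ds.load())
    raise ForcingError(f"unknown forcing format {fmt!r} (csv or netcdf)")


def _result_to_dataset(result: SimulationResult) -> xr.Dataset:
    st, fx = result.states, result.fluxes
    n_layers = st.doc_dissolved.shape[-1]
    coords = {
        "time": st.times,
        "layer": np.arange(1, n_layers + 1),
        "pool": list(POOL_NAMES),
        "doc_class": list(DOC_CLASSES),
    }
    ds = xr.Dataset(
        {
            "soc_pool_stock": (("time", "pool"), st.soc_pools[1:]),
            "doc_dissolved": (("time", "doc_class", "layer"), st.doc_dissolved[1:]),
            "doc_adsorbed": (("time", "doc_class", "layer"), st.doc_adsorbed[1:]),
            "doc_production": (("time", "pool", "layer"), fx.production),
            "doc_decomposition": (("time", "doc_class", "layer"), fx.dec_doc),
            "doc_leaching": (("time", "layer"), fx.leach),
            "co2_soc": (("time",), fx.co2_soc),
            "co2_doc": (("time",), fx.co2_doc),
            "conc_surface": (("time",), st.conc_surface),
            "conc_subsurface": (("time",), st.conc_sub),
        },
        coords=coords,
    )
    for v in ("soc_pool_stock", "doc_dissolved", "doc_adsorbed"):
        ds[v].attrs["units"] = "g C m-2"
    for v in ("doc_production", "doc_decomposition", "doc_leaching", "co2_soc", "co2_doc"):
        ds[v].attrs["units"] = "g C m-2 step-1"
    for v in ("conc_surface", "conc_subsurface"):
        ds[v].attrs["units"] = "mg C L-1"
    return ds


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  config: dict | None = None, seed: int | None = None) -> dict[str, Path]:
    """Write a run's per-step CSV, aggregated netCDF and manifest.

    Returns the paths written, keyed 'fluxes_csv', 'states_nc', 'manifest'.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fluxes_csv": out / "fluxes.csv",
        "states_nc": out / "states.nc",
        "manifest": out / "manifest.json",
    }
    result.fluxes.to_dataframe().to_csv(paths["fluxes_csv"], index_label="time")
    _result_to_dataset(result).to_netcdf(paths["states_nc"], engine="scipy")
    write_manifest(paths["manifest"], config=config, seed=seed)
    return paths


def write_manifest(path: str | Path, config: dict | None = None,
                   seed: int | None = None) -> Path:
    """Plain-text provenance record: config echo + hash, seed, version."""
    from . import __version__

    cfg = config or {}
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package": "soildoc",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": cfg,
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
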