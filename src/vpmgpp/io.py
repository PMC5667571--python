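"""NetCDF interchange for cubes and forcing.

Intermediates travel as classic NetCDF (xarray's scipy backend) with
dims (time, y, x) and per-layer (year, composite) coordinates; boolean
masks are stored as int8.  The gap-fill flag layer accompanies the EVI
variable the same way the product's byte QA layer accompanies GPP.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .climate import ClimateForcing
from .grids import GridGeometry
from .indices import ReflectanceCube, VISeries

_ENGINE = "scipy"


def _calendar_coords(calendar):
    years = np.array([y for y, _ in calendar], dtype=np.int32)
    comps = np.array([k for _, k in calendar], dtype=np.int32)
    return {"year": ("time", years), "composite": ("time", comps)}


def _grid_attrs(grid: GridGeometry | None) -> dict:
    if grid is None:
        return {}
    return {
        "lon0": grid.lon0,
        "lat0": grid.lat0,
        "cell_size": grid.cell_size,
    }


def _read_calendar(ds: xr.Dataset):
    return list(zip(ds["year"].values.tolist(), ds["composite"].values.tolist()))


def save_reflectance_cube(cube: ReflectanceCube, path: str | Path,
                          grid: GridGeometry | None = None) -> Path:
    ds = xr.Dataset(
        {
            "blue": (("time", "y", "x"), cube.blue),
            "red": (("time", "y", "x"), cube.red),
            "nir": (("time", "y", "x"), cube.nir),
            "swir": (("time", "y", "x"), cube.swir),
            "qa_word": (("time", "y", "x"), cube.qa_word.astype(np.int32)),
        },
        coords=_calendar_coords(cube.calendar),
        attrs=_grid_attrs(grid),
    )
    ds.to_netcdf(path, engine=_ENGINE)
    return Path(path)


def load_reflectance_cube(path: str | Path) -> ReflectanceCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return ReflectanceCube(
        blue=ds["blue"].values,
        red=ds["red"].values,
        nir=ds["nir"].values,
        swir=ds["swir"].values,
        qa_word=ds["qa_word"].values,
        calendar=_read_calendar(ds),
    )


def save_vi_series(vi: VISeries, path: str | Path,
                   gapfill_flags: np.ndarray | None = None,
                   grid: GridGeometry | None = None) -> Path:
    data = {
        "evi": (("time", "y", "x"), vi.evi),
        "lswi": (("time", "y", "x"), vi.lswi),
        "evi_valid": (("time", "y", "x"), vi.evi_valid.astype(np.int8)),
        "lswi_valid": (("time", "y", "x"), vi.lswi_valid.astype(np.int8)),
    }
    if gapfill_flags is not None:
        data["gapfill_flag"] = (("time", "y", "x"), gapfill_flags.astype(np.int8))
    ds = xr.Dataset(data, coords=_calendar_coords(vi.calendar),
                    attrs=_grid_attrs(grid))
    ds.to_netcdf(path, engine=_ENGINE)
    return Path(path)


def load_vi_series(path: str | Path) -> tuple[VISeries, np.ndarray | None]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    vi = VISeries(
        evi=ds["evi"].values,
        lswi=ds["lswi"].values,
        evi_valid=ds["evi_valid"].values.astype(bool),
        lswi_valid=ds["lswi_valid"].values.astype(bool),
        calendar=_read_calendar(ds),
    )
    flags = ds["gapfill_flag"].values.astype(bool) if "gapfill_flag" in ds else None
    return vi, flags


def save_forcing(forcing: ClimateForcing, path: str | Path,
                 grid: GridGeometry | None = None) -> Path:
    ds = xr.Dataset(
        {
            "par": (("time", "y", "x"), forcing.par),
            "t_day": (("time", "y", "x"), forcing.t_day),
        },
        coords=_calendar_coords(forcing.calendar),
        attrs=_grid_attrs(grid),
    )
    ds.to_netcdf(path, engine=_ENGINE)
    return Path(path)


def load_forcing(path: str | Path) -> ClimateForcing:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return ClimateForcing(
        par=ds["par"].values,
        t_day=ds["t_day"].values,
        calendar=_read_calendar(ds),
    )
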