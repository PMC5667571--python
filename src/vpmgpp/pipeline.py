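"""End-to-end tiled GPP production driver.

Runs the stage chain

    ingest -> gapfill -> lswimax -> climate -> lue -> gpp -> aggregate -> trend

for one tile over a set of years, from a YAML/dict configuration.
Heavy stage outputs are cached as ``.npz`` under ``<workdir>/cache`` so
a rerun (or a CLI invocation of a single later stage) skips completed
work; logging records what ran and what was skipped.  Inputs are either
fabricated by :mod:`vpmgpp.synthetic` (``input.kind: synthetic``) or
read from NetCDF files previously written with :mod:`vpmgpp.io`
(``input.kind: netcdf``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import climate as climate_mod
from . import gapfill as gapfill_mod
from . import io as io_mod
from . import lswi as lswi_mod
from . import lue as lue_mod
from . import model as model_mod
from . import products as products_mod
from . import synthetic as synth_mod
from . import trend as trend_mod
from .compositing import N_COMPOSITES
from .grids import GridGeometry
from .indices import compute_vi_series, decode_qa, mask_bad_observations

log = logging.getLogger("vpmgpp.pipeline")

STAGES = ("ingest", "gapfill", "lswimax", "climate", "lue", "gpp", "aggregate", "trend")

DEFAULT_CONFIG: dict[str, Any] = {
    "workdir": "vpm_run",
    "seed": 0,
    "years": [2000, 2001, 2002],
    "tile": {"lon0": 10.0, "lat0": 45.0, "cell_size": 0.005,
             "n_rows": 50, "n_cols": 50},
    "input": {"kind": "synthetic", "reflectance": None, "climate": None},
    "qa_dialect": "mod09a1_state",
    "gapfill": {"sg_window": 7, "sg_order": 2, "bise_window": 5,
                "bise_recovery_fraction": 0.2, "bise_min_drop_fraction": 0.2,
                "min_valid_fraction": 0.5},
    "lswi": {"substitution": {}, "use_night_lst": False},
    "par": {"fraction": 0.45, "quanta_per_joule": 4.57},
    "parameter_table": None,
    "aggregate": {"resolutions": [0.05], "temporal": ["annual", "monthly"],
                  "area_weighted": False},
    "trend": {"alpha": 0.05},
    "synthetic": {},
    "cache": True,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict) and key not in (
            "substitution", "synthetic", "tile"
        ):
            out[key] = _merge(base[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(source: str | Path | dict | None) -> dict:
    """Validated configuration; unknown keys fail before any computation."""
    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        with open(source) as fh:
            override = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, override)


@dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    config: dict
    grid: GridGeometry
    outputs: dict[str, Any] = field(default_factory=dict)
    product_files: list[tuple[Path, Path]] = field(default_factory=list)


class Pipeline:
    def __init__(self, config: dict | str | Path | None = None):
        self.config = load_config(config)
        tile = self.config["tile"]
        self.grid = GridGeometry(**tile)
        self.workdir = Path(self.config["workdir"])
        self.cache_dir = self.workdir / "cache"
        self.params = lue_mod.BiomeParameters.from_csv(self.config["parameter_table"])
        self._state: dict[str, Any] = {}

    # -- caching helpers ------------------------------------------------
    def _cache_path(self, stage: str) -> Path:
        return self.cache_dir / f"{stage}.npz"

    def _run_stage(self, stage: str, fn):
        path = self._cache_path(stage)
        if self.config["cache"] and path.exists():
            log.info("stage %s: cached, skipped", stage)
            with np.load(path, allow_pickle=False) as npz:
                self._state[stage] = {k: npz[k] for k in npz.files}
            return self._state[stage]
        log.info("stage %s: running", stage)
        result = fn()
        self._state[stage] = result
        if self.config["cache"]:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(path, **result)
        return result

    def _spec(self) -> synth_mod.FixtureSpec:
        overrides = dict(self.config["synthetic"])
        return synth_mod.FixtureSpec(
            seed=self.config["seed"],
            grid=self.grid,
            years=tuple(self.config["years"]),
            **overrides,
        )

    # -- stages ---------------------------------------------------------
    def ingest(self) -> dict:
        def _run():
            kind = self.config["input"]["kind"]
            if kind == "synthetic":
                cube = synth_mod.generate_reflectance_cube(
                    self._spec(), self.config["qa_dialect"]
                ).cube
            elif kind == "netcdf":
                cube = io_mod.load_reflectance_cube(self.config["input"]["reflectance"])
            else:
                raise ValueError(f"unknown input kind {kind!r}")
            vi = compute_vi_series(cube)
            flags = decode_qa(cube.qa_word, self.config["qa_dialect"])
            masked = mask_bad_observations(vi, flags)
            return {
                "evi": masked.evi, "lswi": masked.lswi,
                "evi_valid": masked.evi_valid, "lswi_valid": masked.lswi_valid,
                "snow_ice": flags.snow_ice,
                "years": np.array(sorted({y for y, _ in cube.calendar})),
            }
        return self._run_stage("ingest", _run)

    def _vi_series(self, state: dict):
        from .indices import VISeries
        years = state["years"].tolist()
        calendar = [(y, k) for y in years for k in range(1, N_COMPOSITES + 1)]
        return VISeries(
            evi=state["evi"], lswi=state["lswi"],
            evi_valid=state["evi_valid"].astype(bool),
            lswi_valid=state["lswi_valid"].astype(bool),
            calendar=calendar,
        )

    def gapfill(self) -> dict:
        ingest = self.ingest()

        def _run():
            cfg = self.config["gapfill"]
            filled, flags, ref = gapfill_mod.reconstruct_evi(
                self._vi_series(ingest),
                window=cfg["sg_window"], order=cfg["sg_order"],
                bise_window=cfg["bise_window"],
                bise_recovery_fraction=cfg["bise_recovery_fraction"],
                bise_min_drop_fraction=cfg["bise_min_drop_fraction"],
                min_fraction=cfg["min_valid_fraction"],
            )
            return {
                "evi_filled": filled.evi,
                "gapfill_flag": flags,
                "reference": ref.values,
                "fillable": ref.fillable,
            }
        return self._run_stage("gapfill", _run)

    def lswimax(self) -> dict:
        ingest = self.ingest()

        def _run():
            vi = self._vi_series(ingest)
            submap = {int(k): int(v) for k, v in
                      self.config["lswi"]["substitution"].items()}
            vi = lswi_mod.substitute_missing_years(vi, submap)
            years = ingest["years"].tolist()
            n_years = len(years)
            shape = vi.lswi.shape[1:]
            snowfree = ~ingest["snow_ice"].astype(bool)
            raw = np.empty((n_years,) + shape)
            lswi_stack = vi.lswi.reshape(n_years, N_COMPOSITES, *shape)
            valid_stack = vi.lswi_valid.reshape(n_years, N_COMPOSITES, *shape)
            snow_stack = snowfree.reshape(n_years, N_COMPOSITES, *shape)
            for i in range(n_years):
                raw[i] = lswi_mod.annual_lswi_max(
                    lswi_stack[i], valid_stack[i], snow_stack[i]
                )
            smoothed = lswi_mod.smooth_lswi_max(raw)
            return {"raw_max": raw, "lswi_max": smoothed, "lswi": vi.lswi,
                    "lswi_valid": vi.lswi_valid}
        return self._run_stage("lswimax", _run)

    def climate(self) -> dict:
        def _run():
            kind = self.config["input"]["kind"]
            if kind == "synthetic":
                fix = synth_mod.generate_climate(self._spec())
                dswrf, tmax, tmean = fix.dswrf, fix.tmax, fix.tmean
                lon, lat = fix.lon, fix.lat
            else:
                forcing = io_mod.load_forcing(self.config["input"]["climate"])
                return {"par": forcing.par, "t_day": forcing.t_day}
            forcing = climate_mod.prepare_forcing(
                dswrf, tmax, tmean, lon, lat, self.grid,
                par_fraction=self.config["par"]["fraction"],
                quanta_per_joule=self.config["par"]["quanta_per_joule"],
            )
            return {"par": forcing.par, "t_day": forcing.t_day}
        return self._run_stage("climate", _run)

    def lue(self) -> dict:
        def _run():
            if self.config["input"]["kind"] != "synthetic":
                raise ValueError("lue stage needs synthetic landcover inputs "
                                 "or a custom driver")
            land = synth_mod.generate_landcover_c4(self._spec())
            maps = lue_mod.C4FractionMaps(
                crop_ratio=lue_mod.crop_c4_ratio(land.crop_c4_pct, land.total_crop_pct),
                crop_grid=land.crop_grid,
                natural_ratio=land.natural_ratio,
                natural_grid=land.natural_grid,
            )
            eps0 = lue_mod.epsilon0_map(land.igbp, self.grid, maps, self.params)
            return {"eps0": eps0, "igbp": land.igbp}
        return self._run_stage("lue", _run)

    def gpp(self) -> dict:
        filled = self.gapfill()
        lsw = self.lswimax()
        forcing = self.climate()
        lue_state = self.lue()

        def _run():
            years = self.ingest()["years"]
            n_years = len(years)
            shape = self.grid.shape
            lswi_max_t = np.repeat(lsw["lswi_max"], N_COMPOSITES, axis=0)
            igbp_t = np.broadcast_to(lue_state["igbp"],
                                     (n_years * N_COMPOSITES,) + shape)
            eps0_t = np.broadcast_to(lue_state["eps0"],
                                     (n_years * N_COMPOSITES,) + shape)
            result = model_mod.run_pixels(
                evi=filled["evi_filled"], lswi=lsw["lswi"],
                lswi_max=lswi_max_t,
                t_day=forcing["t_day"], par=forcing["par"],
                igbp=igbp_t, eps0=eps0_t, params=self.params,
            )
            return {"gpp": result.gpp, "t_scalar": result.t_scalar,
                    "w_scalar": result.w_scalar, "fpar_chl": result.fpar_chl}
        state = self._run_stage("gpp", _run)
        self._write_product(state)
        return state

    def _write_product(self, gpp_state: dict) -> list[tuple[Path, Path]]:
        years = self.ingest()["years"].tolist()
        flags = self.gapfill()["gapfill_flag"]
        product_dir = self.workdir / "product"
        product_dir.mkdir(parents=True, exist_ok=True)
        files = []
        t = 0
        for year in years:
            for k in range(1, N_COMPOSITES + 1):
                path = product_dir / f"gpp_{year}_{k:02d}.tif"
                files.append(products_mod.write_gpp_tile(
                    gpp_state["gpp"][t], flags[t], self.grid, path
                ))
                t += 1
        self._product_files = files
        return files

    def aggregate(self) -> dict:
        gpp_state = self.gpp()
        lue_state = self.lue()

        def _run():
            years = self.ingest()["years"].tolist()
            land_mask = np.isin(lue_state["igbp"], self.params.codes)
            cfg = self.config["aggregate"]
            out = {}
            for res in cfg["resolutions"]:
                coarse_8day, coarse = products_mod.aggregate_spatial(
                    gpp_state["gpp"], self.grid, res, land_mask,
                    area_weighted=cfg["area_weighted"],
                )
                key = f"{res}".replace(".", "p")
                out[f"gpp_8day_{key}"] = coarse_8day
                stack = coarse_8day.reshape(len(years), N_COMPOSITES, *coarse.shape)
                if "annual" in cfg["temporal"]:
                    out[f"gpp_annual_{key}"] = np.stack([
                        products_mod.aggregate_temporal(stack[i], years[i], "annual")
                        for i in range(len(years))
                    ])
                if "monthly" in cfg["temporal"]:
                    out[f"gpp_monthly_{key}"] = np.stack([
                        products_mod.aggregate_temporal(stack[i], years[i], "monthly")
                        for i in range(len(years))
                    ])
            return out
        return self._run_stage("aggregate", _run)

    def trend(self) -> dict:
        agg = self.aggregate()

        def _run():
            years = self.ingest()["years"].tolist()
            res = self.config["aggregate"]["resolutions"][0]
            key = f"{res}".replace(".", "p")
            cube = agg[f"gpp_8day_{key}"]
            coarse_shape = cube.shape[1:]
            cube = cube.reshape(len(years), N_COMPOSITES, *coarse_shape)
            slope, pval, sig = trend_mod.trend_raster(
                cube, alpha=self.config["trend"]["alpha"]
            )
            return {"slope": slope, "p_value": pval, "significant": sig}
        return self._run_stage("trend", _run)

    def run(self, until: str = "trend") -> PipelineResult:
        if until not in STAGES:
            raise ValueError(f"unknown stage {until!r}; stages: {STAGES}")
        result = PipelineResult(config=self.config, grid=self.grid)
        for stage in STAGES[: STAGES.index(until) + 1]:
            result.outputs[stage] = getattr(self, stage)()
        result.product_files = getattr(self, "_product_files", [])
        return result


def run_pipeline(config: dict | str | Path | None = None,
                 until: str = "trend") -> PipelineResult:
    """Execute the production chain for one tile; see :class:`Pipeline`."""
    return Pipeline(config).run(until)
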