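# vpmgpp

A tested re-implementation of the Vegetation Photosynthesis Model (VPM)
production pipeline for gross primary production (GPP): from 8-day
surface-reflectance composites and daily reanalysis climate to tiled,
integer-encoded GPP rasters with a gap-fill QA layer, coarse-resolution
aggregates and nonparametric trend maps.

It is aimed at carbon-cycle and remote-sensing researchers who want to run,
modify or audit a light-use-efficiency GPP chain end to end on data they
control — including fully synthetic tiles with known truth, which the package
generates itself.

## The model

VPM estimates GPP as the PAR absorbed by *chlorophyll* times a realized
light-use efficiency:

```
GPP      = PAR × fPAR_chl × ε_g            [g C m⁻² day⁻¹]
fPAR_chl = (EVI − 0.1) × 1.25              clamped to [0, 1]
ε_g      = ε₀ × T_scalar × W_scalar
T_scalar = (T−T_max)(T−T_min) / [(T−T_max)(T−T_min) − (T−T_opt)²]
W_scalar = (1 + LSWI) / (1 + LSWI_max)     clamped to [0, 1]
```

ε₀ is the maximum light-use efficiency, 0.42 g C mol⁻¹ APAR for C3 and
0.63 for C4 vegetation, mixed per pixel as an area-weighted average driven
by static C4 fraction maps (a 0.083° crop map and a 1° natural-vegetation
map). T_min/T_opt/T_max come from a per-biome (IGBP class) lookup table
shipped as `src/vpmgpp/data/biome_parameters.csv`. LSWI_max is the annual
snow-free maximum of LSWI, smoothed as the second largest value within a
centered five-year window.

Around the equations sits the data production machinery:

- **QA screening** of MOD09A1-style reflectance (cloud state bits 0–1,
  aerosol quantity bits 6–7) and EVI/LSWI computation;
- **EVI gap-filling**: per-pixel median seasonal reference curve, BISE
  spike rejection, and linear interpolation + Savitzky–Golay smoothing of
  *seasonal anomalies* rather than raw values, so long gaps follow the
  climatological shape;
- **LSWI preparation**: donor-year substitution for missing acquisitions
  and the five-year second-largest LSWI_max rule;
- **climate forcing**: daytime temperature = (T_max + T_mean)/2, 8-day
  aggregation on the 46-composite MODIS calendar, PAR from shortwave flux,
  bilinear downscaling to the tile grid;
- **products**: int16 GeoTIFF with 0.001 scale factor and paired byte QA
  layer (0 = raw, 1 = gap-filled), land-only spatial aggregation to 0.05°/0.5°,
  day-weighted monthly/annual totals;
- **trends**: seasonal Mann–Kendall test and seasonal Theil–Sen slope.

## Worked example

Run the whole chain on the default synthetic tile (50 × 50 pixels, three
years, ~25 % clustered cloud gaps, four land-cover patches):

```python
import numpy as np
from vpmgpp.pipeline import run_pipeline

res = run_pipeline({"workdir": "vpm_demo", "seed": 1})
gpp = res.outputs["gpp"]["gpp"]          # (3*46, 50, 50)
flags = res.outputs["gapfill"]["gapfill_flag"]
annual = res.outputs["aggregate"]["gpp_annual_0p05"]
print(f"GPP stack: {gpp.shape}, range {np.nanmin(gpp):.2f}-{np.nanmax(gpp):.2f} g C m-2 day-1")
print(f"gap-filled fraction: {flags.mean():.3f}")
print(f"mean annual GPP (0.05 deg, yr 2000): {np.nanmean(annual[0]):.1f} g C m-2 yr-1")
```

prints

```
GPP stack: (138, 50, 50), range 0.00-19.33 g C m-2 day-1
gap-filled fraction: 0.268
mean annual GPP (0.05 deg, yr 2000): 1684.4 g C m-2 yr-1
```

and writes 138 GPP + QA GeoTIFF pairs under `vpm_demo/product/`. The GPP
range is what a productive mid-latitude mixed landscape produces at peak
season; the gap-filled fraction tracks the fixture's cloud probability; the
annual total is the day-weighted sum of the 46 composite means. The same run
is available from the shell:

```
vpm all --config my_config.yaml --seed 1
```

with stage subcommands (`ingest`, `gapfill`, `lswimax`, `climate`, `lue`,
`gpp`, `aggregate`, `trend`) that reuse cached intermediates.

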