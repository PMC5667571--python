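# Methods

## Model

The package implements a light-use-efficiency (LUE) GPP model of the VPM
family. GPP for an 8-day composite is

GPP = PAR · fPAR_chl · ε₀ · T_scalar · W_scalar,

where PAR is photosynthetically active radiation (mol photons m⁻² day⁻¹),
fPAR_chl = (EVI − 0.1) × 1.25 is the fraction of PAR absorbed by chlorophyll,
and ε₀ is the maximum light-use efficiency in g C per mol APAR. The defining
assumptions are (i) absorption by *chlorophyll*, proxied linearly by EVI,
drives photosynthesis rather than whole-canopy absorption; (ii) temperature
and water stress act multiplicatively as dimensionless scalars in [0, 1];
(iii) ε₀ differs only by photosynthetic pathway (C3: 0.42, C4: 0.63), not by
biome, while the temperature response (T_min, T_opt, T_max) is biome-specific.

Clamping decisions: fPAR_chl exceeds 1 for EVI > 0.9 and goes negative below
EVI = 0.1; W_scalar = (1+LSWI)/(1+LSWI_max) exceeds 1 whenever smoothing
leaves LSWI above LSWI_max. Both are clamped to [0, 1], and T_scalar is
forced to 0 outside (T_min, T_max), where the rational form would otherwise
go negative or blow up. These enforce the scalars' stated range; without the
clamps a wet, dense canopy could be credited more than ε₀.

## EVI gap-filling

Per pixel, over all supplied years:

1. **QA mask** — observations that are not (cloud state "clear" AND aerosol
   "low"/"average") are invalidated. Snow/ice is tracked separately and used
   only by the LSWI_max search.
2. **BISE spike rejection** — within each pixel-year, a point whose drop from
   the last accepted value exceeds 20 % of that value is rejected if any
   later valid point within a 5-composite (~40-day) window exceeds the low
   value plus 20 % of the drop. The minimum-drop criterion matters: without
   it the gentle decline into the seasonal trough always "recovers" within
   the window and the trough itself gets stripped, biasing the reference
   upward by ~0.02 EVI on smooth phenologies. Both fractions and the window
   are configurable.
3. **Reference curve** — the median (even count: mean of the central pair) of
   surviving observations per composite index. Composite indices with no
   observation are filled by linear interpolation on the *circular* seasonal
   axis (composite 46 is adjacent to composite 1), and the curve is smoothed
   with the same Savitzky–Golay filter used everywhere (window 7 composites,
   order 2; configurable). A pixel needs valid data in at least half of the
   46 composite indices to be fillable; otherwise it propagates nodata.
4. **Anomaly filling** — each year's deviation from the reference is linearly
   interpolated across its gaps (ends held at the nearest valid value) and
   SG-smoothed; the reference is added back. Filling anomalies instead of raw
   EVI means a long gap follows the climatological green-up/senescence shape
   instead of a chord — the behavior that matters for multi-month outages.
   A year with a single valid observation carries its one anomaly as a
   constant offset; a fully missing year returns the reference.

The gap-fill QA flag is 1 exactly where the output did not come from a
surviving raw observation (QA-masked, BISE-rejected, or missing).

## LSWI and LSWI_max

LSWI is deliberately *not* anomaly-gap-filled: contamination biases it high
(which only relaxes the water scalar), its interannual variance is the
water-stress signal, and smoothing would erase that. Systematically missing
years are instead patched composite-by-composite from a configured donor
year. LSWI_max is the annual maximum over snow-free valid composites — a
composite is snow-free when the QA snow/ice flag is unset and, when a
nighttime LST layer is supplied, the surface stayed above 0 °C (the LST
criterion is an optional belt-and-braces interpretation, off by default in
the pipeline config) — then smoothed by taking the *second largest* annual
maximum within a centered five-year window, truncated at the record ends
(no mirroring). Duplicated maxima count separately; a window with a single
valid value returns it. The second-largest rule removes single-year upward
artifacts without dragging the ceiling down.

## Climate forcing

Daytime temperature is (daily T_max + daily T_mean)/2. Daily fields are
averaged onto the 46-composite calendar (windows start DOY 1, 9, …, 361;
the last window spans 5 days, 6 in leap years), which conserves the annual
day-weighted mean exactly. PAR = dswrf × 0.45 × 4.57 µmol J⁻¹ × 86400 s
× 10⁻⁶; the PAR energy fraction (0.45) and quantum content (4.57 µmol per
joule of PAR) are named configuration constants because ε₀ calibrations are
tied to a specific PAR convention. Spatial downscaling is bilinear
interpolation of coarse cell-center values to pixel centers, with
nearest-edge clamping outside the cell-center hull; temporal aggregation
runs first — both operations are linear, so order does not change the
result, and the coarse-grid average is cheaper.

## C3/C4 mixing

The crop C4 ratio per 0.083° cell is (C4 crop area %) / (total crop area %),
with ratio 0 where no crop exists; the total crop percentage is derived from
the land-cover raster itself (fraction of CRO/CNV pixels per cell). Cropland
and cropland/natural-mosaic pixels read this map; grassland, savanna, woody
savanna and wetland read the 1° natural-C4 map; every other class gets
ratio 0. The effective ε₀ is (1−r)·0.42 + r·0.63 for classes with a defined
C4 value, otherwise the C3 value (woody savanna routes through the natural
map but has no C4 ε₀ in the table, so its ratio is inert). Water, snow/ice,
barren and unclassified pixels carry nodata ε₀ and never produce GPP.

## Trend statistics

Seasonal Mann–Kendall: the S statistic and its tie-corrected variance are
computed within each season (the 46 composites, or 12 months) and summed;
the two-sided p-value uses the normal approximation with continuity
correction (±1 on S). Seasons are assumed independent. The seasonal
Theil–Sen slope is the median of all within-season pairwise slopes pooled
across seasons, per year of the input units. Both are invariant to adding a
per-season constant, which is what makes them safe on strongly seasonal
series. No field-significance or spatial multiple-testing correction is
applied.

## Products

GPP rasters are int16 with scale factor 0.001 g C m⁻² day⁻¹ and sentinel
−9999 (int16 was chosen as the smallest type whose range, ±32.767 after
scaling, covers observed daily GPP; the encode step raises if exceeded).
Every GPP file has a byte QA companion of identical geometry. Spatial
aggregation to 0.05°/0.5° averages land pixels only — coastal cells need no
land-fraction correction when summed — with an optional cos(latitude) area
weighting (off by default; the plain pixel-count mean is the documented
default). Monthly totals split composites straddling month boundaries day
by day, so the twelve monthly values sum exactly to the annual total.

## Synthetic fixtures

The generator fabricates: sinusoidal per-patch EVI phenology with Gaussian
noise; cloud gaps from a first-order Markov chain (stationary probability
0.25, persistence 0.5, giving the clustered multi-composite outages that
stress the anomaly filler); cloud-biased observations (EVI depressed by 0.2,
LSWI raised by 0.1 under flags); band reflectances *inverted exactly* from
the observed indices, so the ingest stage reproduces them to rounding error;
QA words in the MOD09A1 state-QA bit layout; coarse-grid daily climate with
a mid-latitude seasonal cycle (annual mean 10 °C, amplitude 12 °C, shortwave
180 ± 100 W m⁻²) and tmax ≥ tmean by construction; a quadrant land-cover
raster and C4 fraction maps at their native resolutions, with the true
effective ε₀ re-derived by independent straight-line arithmetic. The default
tile is 50 × 50 pixels × 3 years — the full chain runs in a few seconds —
and all generators are pure functions of (spec, seed).

What the fixtures do **not** emulate: real MODIS radiometry and sinusoidal
tile geometry, directional/BRDF effects, correlated noise between bands,
snow-contaminated reflectance spectra, topographic climate structure, and
land-cover change over time. Passing recovery tests therefore demonstrates
algorithmic correctness under the stated noise/gap model, not radiometric
fidelity on real tiles.

## Verification strategy

The GPP equations are dual-routed: `vpmgpp.model` is the implementation;
`vpmgpp.synthetic.true_gpp_oracle` is an independent straight-line recode
with hard-coded constants. On a noise-free, gap-free fixture the full
pipeline's GPP must agree with the oracle evaluated on the pipeline's
prepared forcings to 1 part in 10¹², and the reconstructed EVI must track
the fixture truth to better than 10⁻³ (the residual is the Savitzky–Golay
response to a sinusoid, ~10⁻⁴). Trend statistics are checked against
brute-force all-pairs enumeration on small fixtures and a 1000-replicate
white-noise calibration of the type-I error at α = 0.05 (10 years × 4
seasons). The LSWI_max rule is checked against a sort-based oracle.

## Known limitations

- The BISE parameters (window, recovery fraction, minimum-drop fraction)
  are conventions, not fitted values; aggressive settings can eat real
  abrupt disturbances (fire, harvest) that genuinely persist < 40 days.
- Year-substitution for LSWI assumes the donor year is hydrologically
  similar; drought years patched from wet neighbors understate stress.
- Bilinear climate downscaling adds no orographic detail; mountain tiles
  inherit the coarse-grid lapse-rate smoothing.
- The static C4 maps carry no interannual dynamics, so cropping-system
  change aliases into ε₀ error.
- The seasonal Theil–Sen slope can produce artifacts where the seasonal
  cycle is weak relative to noise (arid regions); no remedy is applied.
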