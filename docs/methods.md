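# Methods

This note documents the models, conventions and numerical choices behind
`envgrid`, and what the synthetic fixtures do and do not establish about
real data.

## Grids and alignment

Every raster is bound to a `GridSpec`: CRS, top-left-corner origin, square
cell size, and shape. Row index increases southward, sampling is
cell-center registered, and extents are half-open `[min, max)`. Two CRSs
appear: UTM zone 32N (EPSG:32632) for the local and country levels and
geographic WGS84 (EPSG:4326) for the continental level. The conversion
between them is the standard transverse-Mercator series on the WGS84
ellipsoid (Snyder's equations), implemented in `envgrid.crs` and verified
by round-trip tests (sub-centimeter over the zone).

Within the UTM levels, all cell sizes are integer multiples or integer
submultiples of 1 km and all layers snap to a fixed master lattice. The
master origins are declared round-kilometer corners (local:
600 000 E / 5 250 000 N; country: 200 000 E / 5 350 000 N); any fixed
round-km corner satisfies the multiples/submultiples rule, so these are
package constants rather than estimated quantities. `align_to_master`
snaps a layer's resolution to the closest multiple-or-submultiple of the
master cell (an explicit target can be passed, e.g. for deliberate
coarsening), places the output origin on the master-anchored lattice at
the coarser of the two spacings, and resamples by nearest-neighbour,
nodata-aware bilinear, or block mean. Bilinear interpolation divides the
interpolated `value*validity` field by the interpolated validity weight,
which preserves constants and keeps nodata from bleeding numeric garbage;
cells with weight below 0.5 are nodata.

`snap_resolution` rounds a native resolution half-up to the nearest whole
kilometer, except where the product registry declares the published target
(27 km for the 0.25° gridded-station precipitation product, 10 km for the
0.1° satellite product — values a single naive degree-to-km conversion
cannot reproduce, hence registry constants).

## Quality filtering

Thermal QC bytes are split into the 2-bit mandatory-QA field (bits 0–1)
and the 2-bit data-quality field (bits 2–3); the upper four bits are
exposed raw but unused by the default policy. The default policy accepts
mandatory-QA codes {0, 1} (good, plus produced-but-check-other-quality),
the common practice for thermal land products; it is configurable. The
default rejected scene-classification classes are no-data/saturated,
cloud shadow, medium- and high-probability cloud and thin cirrus. Scene
eligibility uses a strict comparison: a scene with cloud cover exactly at
the 80 % default is not eligible.

## LST pipeline

Digital numbers scale as `DN × 0.02 − 273.15` (the standard thermal
product convention; factor and offset configurable), with DN 0 as fill.
Two outlier filters run per scene (per date × overpass — the fit is not
pooled across scenes because the lapse gradient has a strong diurnal
cycle):

1. distribution filter: pixels beyond `k·MAD` (default k = 5) of the
   scene median are masked; the MAD is floored at 1e-6 so constant fields
   pass through;
2. lapse filter: ordinary least squares of LST on elevation over jointly
   valid pixels; pixels beyond `k_sigma` residual standard deviations
   (default 3) of the prediction are masked. A zero residual SD retains
   only exact matches; a constant DEM is a degenerate predictor and an
   error.

Reconstruction targets the 200 m DEM grid (a coarser observed layer is
first assigned to the fine cells by nearest neighbour). Gaps receive the
lapse prediction at their elevation plus a residual surface interpolated
from the surviving pixels with a thin-plate spline (smoothing 0 by
default, i.e. exact at anchors). Residual interpolation is 2-D in grid
coordinates; interpolating residuals in 3-D (x, y, elevation) is a noted
extension. For tractability the spline uses at most 1 200 anchors, thinned
by even striding when more survive — the surface remains exact at retained
anchors. When all residuals are below 1e-12 (noiseless linear scenes) the
surface is identically zero, making recovery of masked pixels exact.

8-day composites are nodata-aware per-pixel means over windows starting at
day-of-year 1, 9, 17, … each year, so a non-leap year has 46 windows and
the last window is short. The four daily overpasses are tagged by
satellite × day/night (`TERRA-DAY`, …), which serves as the hour surrogate
in filenames and queries.

## Spectral indices

NDVI and MNDWI are clipped to [−1, 1] and return nodata on zero
denominators; EVI uses the standard coefficients G = 2.5, C1 = 6,
C2 = 7.5, L = 1, is left unclipped, and guards denominators below 1e-6.
Inputs are reflectances in [0, 1]; integer-scaled products should be
divided by their declared scale on read. Note that EVI is *not*
antisymmetric under swapping NIR and Red (its denominator is asymmetric),
unlike the two normalized-difference indices; the property tests reflect
this. The 16-day series is aligned to the 8-day thermal cadence by
inserting the nodata-aware pairwise mean of consecutive images at the
midpoint date, preserving the originals (insertion, not replacement).

## Station data

Provider dialects are declarative `ProviderMapping`s (column names,
strptime date format, per-variable unit scale factors, NA tokens), so new
agencies need configuration, not code. Values are rounded to 9 decimals
after unit conversion, which makes tenths-of-a-unit dialects round-trip
losslessly. QA rules: plausibility ranges (temperature −50…50 °C,
precipitation 0…1000 mm/day, humidity 0…100 %), duplicate collapse
(identical copies; conflicting values reject the whole key), and the
ordering rule TMN2 ≤ TMD2 ≤ TMX2 per station-day. Every rejection carries
a reason, and accepted + rejected always partition the input, so the
cleaning is auditable and idempotent.

Daily precipitation surfaces come from a thin-plate smoothing spline — the
same regularized-spline family GIS tools use for scattered meteorological
data — fitted in kilometer coordinates for conditioning, with smoothing
0.1 (field units) by default and at least 5 reporting stations required.
Zero smoothing interpolates exactly at the stations and reproduces
constant fields to machine precision (the spline's degree-1 polynomial
tail). Negative interpolated values are floored at zero. Humidity records
are stored and queryable but not interpolated.

## Derived covariates

- GDD: `Σ max(0, (Tmax+Tmin)/2 − Tbase)`; days missing either temperature
  are skipped and counted. Additive over partitioned date ranges.
- De Martonne: `P/(T+10)` annual, `12·p/(t+10)` monthly; undefined (NaN)
  at T ≤ −10 °C.
- Rainy days: inclusive comparison (`prec ≥ threshold`, default 1 mm) by
  declared convention; a strict mode is available.
- Windowed variability: sample SD (n−1 denominator, ≥ 2 observations) and
  Fisher excess kurtosis from population moments (`m4/m2² − 3`, ≥ 4
  observations and non-zero variance; a normal series gives 0, a
  symmetric two-point series −2).
- Bioclim: the 19 standard summaries of monthly tmin/tmax/precipitation.
  Quarters are all 12 wrap-around 3-calendar-month windows; ties pick the
  earliest quarter. BIO4 is 100 × the sample SD of monthly mean
  temperature; BIO15 is 100 × the sample SD of monthly precipitation over
  (mean + 1), the +1 guarding fully arid pixels; BIO3 is NaN where the
  annual range BIO7 is zero. The implementation is vectorized over raster
  stacks and checked against an independent brute-force quarter
  enumeration. Monthly aggregation from daily series uses month means for
  temperature, month sums for precipitation, and marks months with more
  than 20 % of days missing as nodata.
- Land-cover percentages: per zone (integer zone raster or shapely
  polygons with cell-center containment), percentages over valid class
  cells sum to 100; zero-cell zones yield an empty breakdown.

## Synthetic fixtures

The generators emulate the study conditions end to end with a single
integer seed: a sum-of-Gaussian-hills DEM (1 500 m relief), LST scenes
built as overpass-specific sea-level temperature plus the standard
environmental lapse rate (−0.0065 °C/m) plus a smooth anomaly, observed
with 1 °C Gaussian noise and 30 % cloud-flagged pixels; a 10 m
multispectral tile with painted vegetation/water patches whose reflectance
signatures pin the index signs and magnitudes (vegetation NDVI ≈ 0.84,
water the only region with positive MNDWI); and a 40-station network
sampled from a smooth precipitation field and re-serialized into two
distinct provider dialects. Default tiles are small (60×60 at 200 m,
240×240 at 10 m) so the full pipeline runs in seconds; sizes are
configurable upward.

What passing tests show: the algorithms are correct on fields whose
structure (smooth truth + Gaussian noise + random gaps) matches their
modeling assumptions, and recovery error is quantified against known
truth. What they do not show: behaviour under real-data pathologies —
spatially correlated cloud masks, sensor striping, temperature inversions
that defeat the linear lapse model, non-stationary precipitation fields —
nor swath geometry or atmospheric effects, which are out of scope.

## Known limitations

- The lapse model is a single linear fit per scene; inversions and
  coastal effects violate it and land in the residual surface.
- Residual interpolation is 2-D; 3-D (with elevation) is future work.
- Humidity surfaces are not produced.
- The catalog is filesystem-backed; checksums are computed lazily on
  request and not stored.
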