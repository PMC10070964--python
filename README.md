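# envgrid

Harmonized environmental rasters and ground-station data for epidemiology.

Epidemiological models of vector-borne disease (West Nile virus, avian
influenza, mosquito population dynamics) need environmental covariates —
land surface temperature, vegetation and water indices, precipitation — on
a common spatial and temporal frame, not as the heterogeneous raster and
table products the providers distribute. `envgrid` implements the
processing core of such a system:

- **Multi-level grids.** Three geographical levels (local / country in
  UTM32N, continental in WGS84). All UTM layers use cell sizes that are
  integer multiples or submultiples of 1 km and snap to a fixed master
  lattice, so cells coincide across products (`envgrid.grids`).
- **Quality filtering.** Bit-encoded QC bands are decoded
  (bits 0–1 mandatory QA, bits 2–3 data quality), scene-classification
  layers remove cloud and shadow pixels, and whole scenes are eligible only
  below a strict 80 % cloud-cover threshold (`envgrid.qc`).
- **LST reconstruction.** Daily thermal acquisitions (two satellites ×
  day/night) are scaled to °C (DN × 0.02 − 273.15), outlier-filtered
  against the scene distribution (median ± k·MAD) and against the
  altitudinal lapse regression `LST = a + b·elev`, then made gap-free on
  the 200 m DEM grid: each missing pixel receives the lapse prediction at
  its elevation plus a thin-plate residual surface anchored at the
  surviving observations. Coarser levels get nodata-aware 8-day composites
  (`envgrid.lst`).
- **Spectral indices.** NDVI = (NIR−Red)/(NIR+Red),
  EVI = 2.5 (NIR−Red)/(NIR + 6 Red − 7.5 Blue + 1),
  MNDWI = (Green−SWIR)/(Green+SWIR); 16-day composite series are aligned
  to the 8-day cadence by inserting pairwise midpoints (`envgrid.indices`).
- **Station meteorology.** Provider-specific daily tables are harmonized
  into a common schema (TMX2/TMD2/TMN2, PREC, UMX2/UMD2/UMN2) through
  declarative dialect mappings, QA-cleaned (ranges, duplicates,
  TMN2 ≤ TMD2 ≤ TMX2), and daily precipitation is interpolated to the 1 km
  grid with a thin-plate smoothing spline (`envgrid.stations`).
- **Derived covariates.** Growing degree days
  GDD = Σ max(0, (Tmax+Tmin)/2 − Tbase), De Martonne aridity P/(T+10),
  rainy-day counts, windowed SD and excess kurtosis of raster series, the
  19 bioclimatic variables BIO1–BIO19 from monthly climate, and per-zone
  land-cover percentages (`envgrid.derived`).
- **Catalog.** Artifacts are named
  `{VARIABLE}_{LEVEL}_{YYYYMMDD}[_{TAG}].tif` so a plain directory is
  queryable by variable, level, date range and overpass tag, and product
  cadences (daily, 8-day, 16-day) support completeness reports
  (`envgrid.catalog`).
- **Synthetic fixtures.** Seeded generators emulate every input — a
  Gaussian-hill DEM, elevation-lapsed LST with cloud gaps, multispectral
  patches with known index signatures, and two station-table dialects —
  shipping their ground truth so every stage is testable without downloads
  (`envgrid.synth`).

## Worked example

```python
import numpy as np
from envgrid import synth, lst

cfg = synth.FixtureConfig(seed=1)          # 60x60 cell, 200 m tile; 30% clouds
dem = synth.make_dem(cfg)
scene = synth.make_lst_scene(cfg, dem)     # 4 overpasses + QC + ground truth

model = lst.fit_lapse_model(scene.acquisitions[0].layer, dem)
print(f"lapse slope {model.slope:.5f} degC/m, residual SD {model.residual_sd:.2f} degC")

layers = lst.process_local_day(scene.acquisitions, scene.qc, dem)
print(len(layers), "gap-free layers,",
      sum(int(l.nodata_mask.sum()) for l in layers), "nodata cells")
for l in layers:
    t = scene.truth[l.hour_tag].values
    print(f"  {l.hour_tag:12s} RMSE vs truth {np.sqrt(((l.values-t)**2).mean()):.2f} degC")
```

prints

```
lapse slope -0.00671 degC/m, residual SD 1.26 degC
4 gap-free layers, 0 nodata cells
  TERRA-DAY    RMSE vs truth 0.95 degC
  TERRA-NIGHT  RMSE vs truth 0.92 degC
  AQUA-DAY     RMSE vs truth 0.91 degC
  AQUA-NIGHT   RMSE vs truth 0.92 degC
```

The fitted slope recovers the −0.0065 °C/m lapse rate the scene was painted
with (to within its sampling error), and the reconstructed fields sit within
the 1 °C observation noise of the hidden truth even though 30 % of each
scene was cloud-masked.

A command-line interface chains the stages on a materialized workspace:

```bash
envgrid fixtures --seed 1 --out demo/
envgrid lst      --workspace demo/ --out out/
envgrid indices  --workspace demo/ --out out/
envgrid meteo    --workspace demo/ --out out/
envgrid report   --root out/ --variable LST --level LOCAL \
                 --source MODIS --start 2020-07-01 --end 2020-07-01
```

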