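# urbannature

Urban green and natural space assessment against the C40 Urban Nature
Declaration (UND) targets, with conversion of those targets onto the NDVI
scale used by epidemiological exposure–response functions.

Access to urban green and blue space is associated with better health, but
policy targets are written in terms of *area* ("30–40% of the city should
be greenspace") and *access* ("70% of the population within a 15-minute
walk of natural space"), while the health literature measures exposure as
the normalized difference vegetation index,

```
NDVI = (NIR − VIS) / (NIR + VIS)  ∈ [−1, 1].
```

This package implements the full chain needed to bridge the two, for
anyone evaluating a city — urban health researchers, exposure scientists,
or city analysts — from 10 m landcover and satellite band rasters:

1. **Characterize** — per-pixel NDVI from near-infrared and visible-red
   reflectance, composited over a year to the greenest pixel (per-pixel
   maximum, which removes clouds and seasonality); binary greenspace from
   the 7 vegetated WorldCover classes (trees, shrubland, grassland,
   cropland, herbaceous wetland, mangroves, moss/lichen); natural space =
   greenspace + open water, and a fused *natural-space NDVI* layer with
   water (and stray negative-NDVI pixels) set to 1.
2. **Evaluate** — the *Quality Total Cover* (QTC) target from the city
   mean of 100 m green-area fractions, and the *Equitable Spatial
   Distribution* (ESD) target from the population-weighted fraction with
   ≥ 0.5 ha of contiguous natural space within a 1,000 m buffer (the
   WHO public-greenspace minimum and a 15-minute walk, respectively).
3. **Convert** — per-city OLS of 100 m NDVI on green-area fraction,
   evaluated at 30%/40% green to express QTC as an NDVI level; the fit at
   75% green sets an NDVI threshold that rebuilds the access metric on
   the NDVI scale, and a second OLS converts the 70% ESD level.

A synthetic-city generator (spatially correlated landcover with a
built-up core, class-conditional NDVI with seasons and clouds, adult
population concentrated downtown, an irregular boundary) provides fully
reproducible inputs with known ground truth, so the whole pipeline runs
at desk scale with no downloads.

## Worked example

Declare a run in YAML — either paths to your own rasters or a synthetic
recipe — and run it:

```yaml
# demo.yaml
recipe:
  shape: [1000, 1000]   # 10 x 10 km at 10 m
  seed: 7
output_dir: demo_out
```

```text
$ urbannature run -c demo.yaml
green fraction      0.381
natural fraction    0.382
mean NDVI           0.277
pop access fraction 0.847
QTC pass 30/40      True/False
ESD pass            True
NDVI at 30%/40%     0.241/0.286  (R2 0.887, RMSE 0.075)
ESD at 70%          0.878  (R2 0.402, RMSE 0.134)
report written to demo_out/report.json
```

Reading: 38.1% of this city's area is greenspace, so it meets the lower
(30%) but not the upper (40%) QTC level, and 84.7% of residents live
within a 15-minute walk of a ≥ 0.5 ha natural area, passing the 70% ESD
target. The city-specific regression (R² 0.887) says that *reaching* 30%
green corresponds to a city NDVI of 0.241 — the number that can be fed
into an NDVI-based exposure–response function to estimate the health
benefit of meeting the target. Intermediate rasters (composite NDVI,
binary masks, access layers) and a `report.json`/`report.csv` pair are
written to `output_dir`; `urbannature simulate` writes a synthetic city's
input layers as GeoTIFFs, and the same computation is available as a
library (`urbannature.run_pipeline`, or the individual stage functions).

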