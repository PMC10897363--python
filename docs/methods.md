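# Methods

## Overview

The package evaluates a city's green and natural space against the two
C40 Urban Nature Declaration targets and converts those targets onto the
NDVI scale. The computation has three stages: characterization of the
city's natural space at the 10 m native resolution, evaluation of the
area (Quality Total Cover, QTC) and access (Equitable Spatial
Distribution, ESD) targets at 100 m, and per-city regression conversion
of both targets to NDVI levels. All layers travel as axis-aligned rasters
in a projected metre-unit CRS; nothing is reprojected, and grids that do
not share a lattice and CRS tag are rejected.

## Characterization (10 m)

**NDVI and compositing.** NDVI = (NIR − VIS)/(NIR + VIS) per pixel, from
the near-infrared and visible-red reflectance bands of each imaging
date. Reflectance scaling cancels, so digital numbers and 0–1 floats are
both acceptable. Pixels where NIR + VIS = 0 are undefined and become
nodata rather than 0. The annual layer is the per-pixel maximum across
dates ("greenest pixel"), which suppresses clouds and seasonal low
points without an explicit cloud mask; a pixel is nodata only if it is
missing on every date.

**Landcover masks.** Greenspace is the union of the 7 vegetated
WorldCover classes (trees, shrubland, grassland, cropland, herbaceous
wetland, mangroves, moss/lichen); built-up, bare/sparse, snow/ice and
open water are excluded. Although the QTC target text admits "permeable
surfaces", only vegetated classes are counted here; the class set is
configurable. Natural space adds the open-water class. Class codes
default to the ESA WorldCover numbering and are configurable.

**Natural-space NDVI.** The fused layer used on the NDVI side of the ESD
conversion sets open-water pixels to 1 (blue space treated as maximally
natural) and likewise any non-water pixel whose composite NDVI is
negative, which indicates water or residual cloud. All other pixels keep
their composite value.

## Target evaluation (100 m)

Binary 10 m layers are aggregated to 100 m by the area-weighted mean over
each 10 × 10 block: the coarse value is the fraction of valid fine cells
that are 1. The 100 m lattice is anchored at the raster origin. Partial
edge blocks and blocks containing nodata average over their valid cells
only; a coarse cell is nodata only when its whole block is. City means
are taken over the 100 m cells inside the boundary mask, which is binary
at cell level (no fractional boundary weighting).

**QTC.** City green fraction = unweighted mean of 100 m green fractions;
pass thresholds 0.30 and 0.40, inclusive (≥).

**ESD.** At 10 m, natural-space patches are connected components
(8-connected by default; configurable) and patches below 0.5 ha
(5,000 m²) are discarded — the WHO minimum for a public green space,
used to exclude most private lawns and gardens. A pixel has access if
the *total* remaining natural area within a 1,000 m Euclidean buffer of
its centre (≈ a 15-minute walk) reaches 0.5 ha; slivers of large patches
inside the buffer count, and a stricter `single_patch` mode requiring one
patch alone to place 0.5 ha inside the buffer is available. The buffer sum is an FFT
convolution with a discrete disk kernel (cell centres within the radius,
focal cell included), rounded back to integer cell counts, so flags are
exactly those of a brute-force distance computation; area outside the
raster contributes nothing. Patch filtering and buffering run on the
full raster, not the masked subset, so parkland just outside the
boundary still serves residents near the edge. Flags aggregate to 100 m
fractions, and the city score is Σ(pop × access)/Σ(pop) over city cells;
with no population raster (or zero total population) the
population-weighted score is reported missing rather than guessed.

## Conversion to the NDVI scale

**QTC.** Per city, OLS of 100 m composite NDVI on 100 m green fraction
over masked cells, evaluated at green fractions 0.30 and 0.40. The
target text names green area as the regressand, but every use of the
model predicts NDVI *from* a green-area level, so NDVI is the response
by default; a switch provides the literal orientation. Reported fit
statistics are R² = 1 − SS_res/SS_tot and RMSE = √(SS_res/n) — the plain
residual RMS (denominator n, not n − 2), matching the interpretation of
RMSE as the typical gap between predicted and observed NDVI. A constant
response yields R² = 0 with a warning; a constant predictor (uniformly
green or built city) is an error surfaced to the caller. Predictions are
not clamped to [−1, 1]; extrapolations warn.

**ESD.** The QTC fit evaluated at 75% green (90% and 100% are also
computed) sets the NDVI threshold above which a 10 m pixel of the fused
layer counts as natural; fused water pixels are 1 and therefore always
natural. The access computation is repeated on this NDVI-based layer,
and a second per-city OLS relates the two 100 m access fractions with
the NDVI-based fraction as response, so its value at landcover access
0.70 expresses the ESD target on the NDVI-based measure. The 75% level
is the default because the access-vs-access regressions fit best there;
the orientation is again switchable. The relation being between two
access fractions (not pixel NDVI) is a deliberate reading of an
under-specified step; the alternative — inverting the threshold relation
to quote a pixel NDVI — is not asserted.

## Synthetic cities

The generator emulates the four real inputs at desk scale with known
truth; one seed drives a single `numpy` generator, so bundles are
bit-reproducible.

* **Landcover**: a Gaussian random field smoothed to a 400 m correlation
  length plus a radial trend (weight 3) that concentrates built-up
  downtown, rank-thresholded so class proportions are exact. Default
  mixture: 50% vegetated (18% trees, 17% grassland, 6% cropland, 5%
  wetland, 4% shrubland), 45% built-up, 5% bare — a mid-density city in
  the range observed globally. Water is stamped as two contiguous 3 ha
  bodies. The district-scale correlation matters: it creates core areas
  more than 1 km from any sizeable park, giving the access layer the
  spatial variation real cities show.
* **NDVI**: per class mean (trees 0.75, mangroves 0.70, cropland 0.60,
  shrubland/wetland 0.55, grassland 0.50, moss 0.35, built-up 0.15, bare
  0.10, snow 0.05, water −0.20 pre-fusion) plus smooth spatial noise
  (sd 0.05), minus a per-date seasonal depression (0, 0.15, 0.30, 0.45
  over four dates). Clouds hit 20% of pixels per date and depress NDVI
  by 0.8 — a darkening, not a gap — because the pipeline removes clouds
  by max-compositing, not masking. Bands are synthesized as
  nir = (1+v)/2, vis = (1−v)/2, so NDVI inversion is exact and
  reflectances stay in [0, 1].
* **Population**: one million adults at 100 m, proportional to
  (built-up fraction + 0.02)² times lognormal noise, zero outside the
  city, normalized to the total. Only an adult surface is modelled, as
  greenspace–mortality exposure–response functions are estimated for
  adults.
* **Boundary**: a tapered noise field thresholded to cover 65% of the
  raster, drawn at 100 m and replicated to 10 m so the two resolutions
  agree exactly.

`stamp_geometry` overwrites exact-cell-count disks or strips of one
class (NDVI set to the class mean, clouds cleared there), which makes
patch-filter and buffer fixtures analytic: a stamped 5,000 m² disk is
exactly at the 0.5 ha threshold, and around an isolated minimum-size
patch a pixel has access iff the whole patch lies within its buffer.

What the generator does *not* emulate: georeferencing pathologies
(reprojection, misaligned lattices beyond what the error paths test),
sensor radiometry and atmospheric effects, cloud shadows, landcover
classification error (WorldCover is ~74% accurate; classes here are
exact), demographic structure, and the heavy bimodality of real 100 m
green fractions. Passing tests therefore demonstrate correctness of the
computation and recoverability of known structure — not that any real
city would yield these particular numbers.

## Numerical choices and problem sizes

* Threshold comparisons (green fraction, access, NDVI threshold) are all
  inclusive (≥).
* The FFT focal sum is rounded to the nearest integer before
  thresholding; counts are bounded by the kernel size (~31,000), far
  below where double-precision FFT error (~1e-9 relative) could flip a
  rounding.
* Buffer radii beyond the raster diagonal are clamped to it (every cell
  already sees the whole raster).
* Aggregation uses NaN-aware means on a float64 working copy; binary
  layers are uint8/int16 with −1 as the nodata code.
* Default experiment sizes: the study city is 1,000 × 1,000 cells
  (10 × 10 km) — large enough for ~6,500 100 m city cells and stable
  regressions; the reproducibility check runs at 2,000 × 2,000
  (20 × 20 km); oracle cross-checks use 50 × 50 grids where brute-force
  O(n²) comparison is exact and cheap; regression recovery uses 20
  cities of 10,000 100 m cells.
* GeoTIFF I/O is implemented on tifffile with the standard GeoTIFF tags
  (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA); files
  declaring a geographic (degree) CRS are rejected, since every distance
  and area in the method is metric.

## Known limitations

* The ESD conversion inherits the under-specification discussed above;
  both regression orientations are available but only one is default.
* Access is Euclidean-buffer based; street-network walkability, public
  vs private tenure, and cycling access are out of scope.
* The regression machinery is plain OLS per city — no spatial
  autocorrelation correction, so R² and standard errors are optimistic
  where residuals are spatially structured (true of the method, not just
  this implementation).
* City means include every 100 m cell whose block has at least one valid
  10 m pixel; cells entirely nodata at 10 m are excluded.
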