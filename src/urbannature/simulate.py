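"""Synthetic cities with recoverable ground truth.

Real inputs to the pipeline are a 10 m WorldCover-style landcover raster,
a year of Sentinel-2-style band pairs, a 100 m population raster, and an
urban-boundary mask.  This module fabricates all four with the statistical
structure the analysis assumes:

* landcover drawn by rank-thresholding a spatially autocorrelated Gaussian
  field into the 11 classes at prescribed mixture proportions, with water
  bodies stamped as contiguous blobs;
* per-date NDVI = class mean + smooth spatial noise - seasonal depression,
  with random cloud hits simulated as strong NDVI depressions (greenest-
  pixel compositing, not masking, is what removes clouds downstream);
* band pairs built by inverting the NDVI formula, nir = (1+v)/2 and
  vis = (1-v)/2, so computing NDVI on the synthetic bands returns the
  target field exactly and reflectances stay in [0, 1];
* adult population placed at 100 m, concentrated in built-up cells and
  normalised to a city total;
* an irregular city boundary from a tapered noise field.

Everything derives from a single seed through one named generator, so a
bundle is bit-reproducible.  ``stamp_geometry`` overwrites exact-area
shapes (disk/strip) of a chosen class, giving analytic fixtures for the
patch-size filter and the access buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import CityMask, Grid, block_aggregate
from .landcover import GREEN_CLASSES, WORLDCOVER_CODES, LandcoverScheme
from .ndvi import BandPair

__all__ = [
    "CityRecipe",
    "CityBundle",
    "generate_city",
    "stamp_geometry",
    "synthesize_linear_city",
    "DEFAULT_CLASS_NDVI",
]

#: Peak-season NDVI means per landcover class (water is pre-fusion).
DEFAULT_CLASS_NDVI: dict[str, float] = {
    "trees": 0.75,
    "shrubland": 0.55,
    "grassland": 0.50,
    "cropland": 0.60,
    "herbaceous_wetland": 0.55,
    "mangroves": 0.70,
    "moss_lichen": 0.35,
    "built_up": 0.15,
    "bare_sparse": 0.10,
    "snow_ice": 0.05,
    "open_water": -0.20,
}

#: Landcover mixture of a mid-density city: ~50% vegetated, ~45% built-up
#: and bare, water added separately as contiguous bodies.
DEFAULT_MIXTURE: dict[str, float] = {
    "trees": 0.18,
    "shrubland": 0.04,
    "grassland": 0.17,
    "cropland": 0.06,
    "built_up": 0.45,
    "bare_sparse": 0.05,
    "snow_ice": 0.0,
    "open_water": 0.0,
    "herbaceous_wetland": 0.05,
    "mangroves": 0.0,
    "moss_lichen": 0.0,
}


@dataclass(frozen=True)
class CityRecipe:
    """Parameters of one synthetic city.

    Defaults draw a 10 x 10 km mid-density city: half vegetated, two small
    lakes, four imaging dates spanning the growing season with 20% cloud
    hits per date, and one million adults packed toward built-up blocks.
    """

    shape: tuple[int, int] = (1000, 1000)  # 10 m cells
    seed: int = 0
    corr_length: float = 40.0  # cells; landcover districts span ~400 m
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    water_bodies: int = 2
    water_body_area_m2: float = 30_000.0
    class_ndvi_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_NDVI)
    )
    ndvi_spatial_sd: float = 0.05
    n_dates: int = 4
    seasonal_depression: tuple[float, ...] = (0.0, 0.15, 0.30, 0.45)
    cloud_prob: float = 0.2
    cloud_depression: float = 0.8
    pop_total: float = 1_000_000.0
    pop_concentration: float = 2.0
    core_built_weight: float = 3.0  # radial trend pushing built-up into the core
    boundary_irregularity: float = 0.3
    city_area_fraction: float = 0.65
    cell_size: float = 10.0
    crs_tag: str = "EPSG:32633"

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"mixture proportions must sum to 1, got {sum(self.mixture.values())}"
            )
        if set(self.mixture) - set(WORLDCOVER_CODES):
            raise ValueError("mixture names unknown landcover classes")
        if self.n_dates < 1:
            raise ValueError("need at least one imaging date")
        if len(self.seasonal_depression) != self.n_dates:
            raise ValueError("one seasonal depression per date required")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must lie in [0, 1]")
        if self.water_bodies > 0:
            r_cells = math.sqrt(self.water_body_area_m2 / math.pi) / self.cell_size
            if 2 * r_cells + 2 > min(self.shape):
                raise ValueError("shape too small for the requested water bodies")


@dataclass
class CityBundle:
    """All synthetic layers for one city plus the generating truth.

    ``ndvi_dates`` are the per-date target NDVI fields (what a perfect
    sensor would measure, clouds and season included); band pairs are
    derived views of them.  ``ground_truth`` records the quantities the
    pipeline should recover.
    """

    landcover: Grid
    ndvi_dates: list[np.ndarray]
    clear_ndvi: Grid
    cloud_masks: list[np.ndarray]
    population: Grid
    mask10: CityMask
    mask100: CityMask
    ground_truth: dict
    recipe: CityRecipe

    def band_pairs(self) -> list[BandPair]:
        """Reflectance pairs such that NDVI inversion is exact."""
        pairs = []
        for d, v in enumerate(self.ndvi_dates):
            nir = self.landcover.with_values((1.0 + v) / 2.0)
            vis = self.landcover.with_values((1.0 - v) / 2.0)
            pairs.append(BandPair(nir=nir, vis=vis, date_tag=f"date{d:02d}"))
        return pairs


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


#: Field-rank order for class assignment: vegetated classes sit at the low
#: end and built-up at the high end, so adding a core-peaked trend to the
#: field concentrates built-up downtown and greenery toward the edges.
_ASSIGN_ORDER = (
    "trees", "mangroves", "herbaceous_wetland", "shrubland", "grassland",
    "cropland", "moss_lichen", "snow_ice", "open_water", "bare_sparse",
    "built_up",
)


def _rank_classify(field_vals: np.ndarray, mixture: dict[str, float]) -> np.ndarray:
    """Assign classes to cells by field rank at exact mixture proportions."""
    n = field_vals.size
    order = np.argsort(field_vals, axis=None, kind="stable")
    names = [c for c in _ASSIGN_ORDER if mixture.get(c, 0.0) > 0]
    counts = np.array([mixture[c] * n for c in names])
    ints = np.floor(counts).astype(int)
    # distribute remainder cells to the largest fractional parts
    short = n - ints.sum()
    frac_order = np.argsort(-(counts - ints), kind="stable")
    ints[frac_order[:short]] += 1
    codes = np.empty(n, dtype=np.int16)
    start = 0
    for name, k in zip(names, ints):
        codes[order[start : start + k]] = WORLDCOVER_CODES[name]
        start += k
    return codes.reshape(field_vals.shape)


def _disk_cells(
    shape: tuple[int, int], center: tuple[int, int], n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """The ``n_cells`` cells nearest to ``center`` (deterministic tie-break)."""
    r_max = int(math.ceil(math.sqrt(n_cells / math.pi))) + 2
    r0 = np.arange(max(0, center[0] - r_max), min(shape[0], center[0] + r_max + 1))
    c0 = np.arange(max(0, center[1] - r_max), min(shape[1], center[1] + r_max + 1))
    rr, cc = np.meshgrid(r0, c0, indexing="ij")
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    flat = np.stack([d2.ravel(), rr.ravel(), cc.ravel()], axis=1)
    order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0]))
    if n_cells > flat.shape[0]:
        raise ValueError("geometry does not fit within the raster")
    pick = flat[order[:n_cells]]
    return pick[:, 1].astype(int), pick[:, 2].astype(int)


def generate_city(recipe: CityRecipe) -> CityBundle:
    """Draw one complete synthetic city from the recipe's seed."""
    rng = np.random.default_rng(recipe.seed)
    shape = tuple(recipe.shape)
    cs = recipe.cell_size
    scheme = LandcoverScheme()

    # --- city boundary: tapered noise blob at 100 m, replicated to 10 m
    coarse = (math.ceil(shape[0] / 10), math.ceil(shape[1] / 10))
    yy = np.linspace(-1, 1, coarse[0])[:, None]
    xx = np.linspace(-1, 1, coarse[1])[None, :]
    taper = 1.0 - np.hypot(yy, xx)
    noise = _smooth_field(rng, coarse, sigma=max(2.0, recipe.corr_length / 5))
    bfield = taper + recipe.boundary_irregularity * noise
    cut = np.quantile(bfield, 1.0 - recipe.city_area_fraction)
    m100 = bfield > cut
    m100[coarse[0] // 2, coarse[1] // 2] = True
    m10 = np.repeat(np.repeat(m100, 10, axis=0), 10, axis=1)[: shape[0], : shape[1]]

    # --- landcover from a correlated field plus a built-core radial trend
    lc_field = _smooth_field(rng, shape, sigma=recipe.corr_length)
    fy = np.linspace(-1, 1, shape[0])[:, None]
    fx = np.linspace(-1, 1, shape[1])[None, :]
    core = 1.0 - np.hypot(fy, fx)
    lc = _rank_classify(lc_field + recipe.core_built_weight * core, recipe.mixture)

    # --- water bodies as contiguous disks inside the city
    n_water_cells = int(round(recipe.water_body_area_m2 / cs**2))
    inside = np.argwhere(m10)
    for _ in range(recipe.water_bodies):
        if n_water_cells == 0:
            break
        center = inside[rng.integers(len(inside))]
        rr, cc = _disk_cells(shape, (int(center[0]), int(center[1])), n_water_cells)
        lc[rr, cc] = scheme.water_code

    # --- clear-sky NDVI: class mean + smooth noise
    code_to_mean = {WORLDCOVER_CODES[n]: m for n, m in recipe.class_ndvi_mean.items()}
    v_clear = np.vectorize(code_to_mean.get, otypes=[np.float64])(lc)
    v_clear = v_clear + recipe.ndvi_spatial_sd * _smooth_field(rng, shape, sigma=5.0)
    v_clear = np.clip(v_clear, -1.0, 1.0)

    # --- per-date fields with seasonal depression and cloud hits
    ndvi_dates: list[np.ndarray] = []
    cloud_masks: list[np.ndarray] = []
    for dep in recipe.seasonal_depression:
        clouds = rng.random(shape) < recipe.cloud_prob
        v_d = v_clear - dep
        v_d = np.where(clouds, v_d - recipe.cloud_depression, v_d)
        ndvi_dates.append(np.clip(v_d, -1.0, 1.0))
        cloud_masks.append(clouds)

    # --- adult population at 100 m, concentrated in built-up cells
    landcover = Grid(lc, cell_size=cs, origin=(0.0, 0.0), crs_tag=recipe.crs_tag)
    built10 = landcover.with_values((lc == scheme.class_codes["built_up"]).astype(np.uint8))
    built100 = block_aggregate(built10, 10, "mean").values
    pop_noise = rng.lognormal(mean=0.0, sigma=0.3, size=coarse)
    w = (built100[: coarse[0], : coarse[1]] + 0.02) ** recipe.pop_concentration
    w = w * pop_noise
    w[~m100] = 0.0
    if w.sum() == 0:
        w[m100] = 1.0
    pop = w / w.sum() * recipe.pop_total

    mask10 = CityMask(Grid(m10.astype(np.uint8), cell_size=cs, origin=(0.0, 0.0),
                           crs_tag=recipe.crs_tag))
    mask100 = CityMask(Grid(m100.astype(np.uint8), cell_size=cs * 10,
                            origin=(0.0, 0.0), crs_tag=recipe.crs_tag))
    population = Grid(pop, cell_size=cs * 10, origin=(0.0, 0.0),
                      crs_tag=recipe.crs_tag)

    green_codes = {WORLDCOVER_CODES[c] for c in GREEN_CLASSES}
    in_city = lc[m10]
    truth = {
        "green_fraction_10m": float(np.isin(in_city, list(green_codes)).mean()),
        "natural_fraction_10m": float(
            np.isin(in_city, list(green_codes | {scheme.water_code})).mean()
        ),
        "class_ndvi_mean": dict(recipe.class_ndvi_mean),
        "min_seasonal_depression": float(min(recipe.seasonal_depression)),
        "seed": recipe.seed,
    }

    return CityBundle(
        landcover=landcover,
        ndvi_dates=ndvi_dates,
        clear_ndvi=landcover.with_values(
            v_clear - min(recipe.seasonal_depression)
        ),
        cloud_masks=cloud_masks,
        population=population,
        mask10=mask10,
        mask100=mask100,
        ground_truth=truth,
        recipe=recipe,
    )


def stamp_geometry(
    bundle: CityBundle,
    shape: Literal["disk", "strip"],
    landcover_class: str,
    size_m2: float,
    location: tuple[int, int],
) -> CityBundle:
    """Overwrite an exact-area region with one landcover class, in place.

    The region covers exactly ``round(size_m2 / cell_area)`` cells — a
    disk grows outward from ``location`` by centre distance, a strip runs
    row-major from it — so patch-area thresholds can be tested at metre
    precision.  NDVI in the region is set to the class mean with no noise
    and no clouds, keeping the stamped geometry analytic.
    """
    if landcover_class not in WORLDCOVER_CODES:
        raise ValueError(f"unknown landcover class {landcover_class!r}")
    cs = bundle.landcover.cell_size
    n_cells = int(round(size_m2 / cs**2))
    if n_cells < 1:
        raise ValueError("size_m2 smaller than one cell")
    gshape = bundle.landcover.shape
    if not (0 <= location[0] < gshape[0] and 0 <= location[1] < gshape[1]):
        raise ValueError(f"location {location} outside the raster")
    if shape == "disk":
        rr, cc = _disk_cells(gshape, location, n_cells)
        if len(rr) < n_cells:
            raise ValueError("disk does not fit within the raster")
    elif shape == "strip":
        flat0 = location[0] * gshape[1] + location[1]
        if flat0 + n_cells > gshape[0] * gshape[1]:
            raise ValueError("strip runs past the end of the raster")
        idx = np.arange(flat0, flat0 + n_cells)
        rr, cc = np.divmod(idx, gshape[1])
    else:
        raise ValueError(f"unknown stamp shape {shape!r}")

    code = WORLDCOVER_CODES[landcover_class]
    mean = bundle.recipe.class_ndvi_mean[landcover_class]
    bundle.landcover.values[rr, cc] = code
    bundle.clear_ndvi.values[rr, cc] = mean - min(bundle.recipe.seasonal_depression)
    for dep, v_d, clouds in zip(
        bundle.recipe.seasonal_depression, bundle.ndvi_dates, bundle.cloud_masks
    ):
        v_d[rr, cc] = np.clip(mean - dep, -1.0, 1.0)
        clouds[rr, cc] = False

    lc = bundle.landcover.values
    m10 = bundle.mask10.bool_array()
    green_codes = {WORLDCOVER_CODES[c] for c in GREEN_CLASSES}
    scheme = LandcoverScheme()
    in_city = lc[m10]
    bundle.ground_truth["green_fraction_10m"] = float(
        np.isin(in_city, list(green_codes)).mean()
    )
    bundle.ground_truth["natural_fraction_10m"] = float(
        np.isin(in_city, list(green_codes | {scheme.water_code})).mean()
    )
    bundle.ground_truth.setdefault("stamps", []).append(
        {"shape": shape, "class": landcover_class, "size_m2": size_m2,
         "location": [int(location[0]), int(location[1])], "n_cells": n_cells}
    )
    return bundle


def synthesize_linear_city(
    seed: int,
    n_cells: int = 10_000,
    intercept: float = 0.1,
    slope: float = 0.5,
    noise_sd: float = 0.05,
    cell_size: float = 100.0,
) -> tuple[Grid, Grid, CityMask]:
    """100 m green-fraction and NDVI grids with a known linear relation.

    Green fractions are uniform on [0, 1]; NDVI = intercept + slope x
    fraction + Gaussian noise.  Used for regression parameter-recovery
    experiments where the implied prediction at any green level is known
    analytically.
    """
    rng = np.random.default_rng(seed)
    side = int(math.ceil(math.sqrt(n_cells)))
    g = rng.uniform(0.0, 1.0, size=(side, side))
    v = intercept + slope * g + rng.normal(0.0, noise_sd, size=(side, side))
    mask_arr = np.zeros((side, side), dtype=np.uint8)
    mask_arr.ravel()[:n_cells] = 1
    gg = Grid(g, cell_size=cell_size)
    vv = Grid(v, cell_size=cell_size)
    mask = CityMask(Grid(mask_arr, cell_size=cell_size))
    return gg, vv, mask
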