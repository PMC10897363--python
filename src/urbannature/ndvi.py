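"""NDVI computation, greenest-pixel compositing, and the natural-space layer.

NDVI = (NIR - VIS) / (NIR + VIS) from the near-infrared (Sentinel-2 B8)
and visible red (B4) reflectances, in [-1, 1].  A year of per-date NDVI
layers is reduced to the per-pixel maximum ("greenest pixel"), which
removes clouds and seasonal low points without an explicit cloud mask.
The natural-space NDVI layer then forces open-water pixels — and stray
negative-NDVI pixels, which indicate water or residual cloud — to 1, the
top of the scale, so blue space counts as maximally natural.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import Grid
from .landcover import LandcoverScheme

__all__ = [
    "BandPair",
    "compute_ndvi",
    "greenest_composite",
    "fuse_natural_ndvi",
    "threshold_natural",
]


@dataclass
class BandPair:
    """Co-registered NIR and visible-red reflectance rasters for one date.

    Reflectance scaling is irrelevant: NDVI is invariant to a common
    positive rescaling of both bands, so integer digital numbers and
    0-1 floats are equally acceptable.
    """

    nir: Grid
    vis: Grid
    date_tag: str = ""

    def __post_init__(self) -> None:
        self.nir.require_aligned(self.vis, "NIR and VIS bands")
        for name, band in (("NIR", self.nir), ("VIS", self.vis)):
            vals = band.values[band.valid_mask()]
            if np.issubdtype(np.asarray(vals).dtype, np.number) and (vals < 0).any():
                raise ValueError(f"{name} band has negative reflectance values")


def compute_ndvi(bands: BandPair) -> Grid:
    """Per-cell (NIR - VIS) / (NIR + VIS); nodata where undefined.

    A cell is nodata when either band is nodata or when NIR + VIS = 0
    (the ratio is undefined; greenest-pixel compositing normally fills
    such cells from another date).
    """
    nir = bands.nir.astype_float()
    vis = bands.vis.astype_float()
    denom = nir + vis
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (nir - vis) / denom
    out[denom == 0] = np.nan
    return bands.nir.with_values(out, nodata=np.nan)


def greenest_composite(layers: Sequence[Grid]) -> Grid:
    """Per-cell maximum NDVI across dates, ignoring nodata.

    The result is nodata only where every date is nodata.  With one layer
    this is the identity.
    """
    if len(layers) == 0:
        raise ValueError("greenest_composite needs at least one NDVI layer")
    first = layers[0]
    for lay in layers[1:]:
        first.require_aligned(lay, "NDVI layers")
    stack = np.stack([lay.astype_float() for lay in layers])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN cells
        out = np.nanmax(stack, axis=0)
    return first.with_values(out, nodata=np.nan)


def fuse_natural_ndvi(
    ndvi: Grid, landcover: Grid, scheme: LandcoverScheme | None = None
) -> Grid:
    """Natural-space NDVI: water pixels (and negative-NDVI pixels) set to 1.

    Open-water cells per the landcover take value 1 regardless of their
    NDVI; cells with negative NDVI that the landcover missed are treated
    as blue space too.  All other cells keep their composite NDVI.
    """
    scheme = scheme or LandcoverScheme()
    ndvi.require_aligned(landcover, "NDVI and landcover")
    out = ndvi.astype_float()
    water = landcover.values == scheme.water_code
    out[water] = 1.0
    with np.errstate(invalid="ignore"):
        out[(out < 0) & ~water] = 1.0
    return ndvi.with_values(out, nodata=np.nan)


def threshold_natural(natural_ndvi: Grid, t: float) -> Grid:
    """Binary natural-space mask from the fused NDVI layer at threshold ``t``.

    A cell is natural iff its value >= t (inclusive).  Water cells carry
    value 1 in the fused layer, so they stay natural for any t <= 1.
    Nodata propagates.
    """
    if not -1.0 <= t <= 1.0:
        raise ValueError(f"NDVI threshold must lie in [-1, 1], got {t}")
    vals = natural_ndvi.astype_float()
    with np.errstate(invalid="ignore"):
        out = (vals >= t).astype(np.int16)
    nodata = None
    if np.isnan(vals).any():
        out[np.isnan(vals)] = -1
        nodata = -1
    return natural_ndvi.with_values(out.astype(np.int16), nodata=nodata)
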