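"""Binary greenspace / natural-space classification of WorldCover landcover.

Greenspace is the union of the seven vegetated WorldCover classes (trees,
shrubland, grassland, cropland, herbaceous wetland, mangroves, moss &
lichen); built-up, bare/sparse, snow/ice and open water are excluded.
Natural space additionally counts open water (blue space).  Class codes
follow the ESA WorldCover convention by default but are configurable,
since other landcover products use different numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = [
    "LandcoverScheme",
    "WORLDCOVER_CODES",
    "GREEN_CLASSES",
    "classify_green",
    "classify_natural",
]

#: ESA WorldCover v100/v200 class numbering.
WORLDCOVER_CODES: dict[str, int] = {
    "trees": 10,
    "shrubland": 20,
    "grassland": 30,
    "cropland": 40,
    "built_up": 50,
    "bare_sparse": 60,
    "snow_ice": 70,
    "open_water": 80,
    "herbaceous_wetland": 90,
    "mangroves": 95,
    "moss_lichen": 100,
}

#: The seven vegetated classes counted as greenspace.
GREEN_CLASSES: frozenset[str] = frozenset(
    {
        "trees",
        "shrubland",
        "grassland",
        "cropland",
        "herbaceous_wetland",
        "mangroves",
        "moss_lichen",
    }
)


@dataclass(frozen=True)
class LandcoverScheme:
    """Mapping from landcover class names to integer codes plus the green set.

    ``green_classes`` may be overridden (e.g. to drop cropland, or to admit
    permeable surfaces mapped to a custom class); ``water_class`` names the
    blue-space class folded into natural space.
    """

    class_codes: dict[str, int] = field(default_factory=lambda: dict(WORLDCOVER_CODES))
    green_classes: frozenset[str] = GREEN_CLASSES
    water_class: str = "open_water"

    def __post_init__(self) -> None:
        codes = list(self.class_codes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("landcover class codes must be unique")
        unknown = set(self.green_classes) - set(self.class_codes)
        if unknown:
            raise ValueError(f"green classes not in scheme: {sorted(unknown)}")
        if self.water_class not in self.class_codes:
            raise ValueError(f"water class {self.water_class!r} not in scheme")

    @property
    def green_codes(self) -> np.ndarray:
        return np.array(sorted(self.class_codes[c] for c in self.green_classes))

    @property
    def water_code(self) -> int:
        return self.class_codes[self.water_class]

    @property
    def all_codes(self) -> np.ndarray:
        return np.array(sorted(self.class_codes.values()))


def _check_codes(landcover: Grid, scheme: LandcoverScheme) -> None:
    vals = landcover.values[landcover.valid_mask()]
    known = np.isin(vals, scheme.all_codes)
    if not known.all():
        bad = sorted(set(np.asarray(vals)[~known].tolist()))
        raise ValueError(f"unknown landcover code(s): {bad}")


def _binary_from_codes(landcover: Grid, codes: np.ndarray) -> Grid:
    valid = landcover.valid_mask()
    out = np.where(np.isin(landcover.values, codes), 1, 0).astype(np.uint8)
    nodata = None
    if not valid.all():
        out = out.astype(np.int16)
        out[~valid] = -1
        nodata = -1
    return landcover.with_values(out, nodata=nodata)


def classify_green(landcover: Grid, scheme: LandcoverScheme | None = None) -> Grid:
    """Binary greenspace mask: 1 on the seven vegetated classes, else 0.

    Nodata propagates.  Raises ``ValueError`` naming any code absent from
    the scheme, which usually signals a mismatched landcover product.
    """
    scheme = scheme or LandcoverScheme()
    _check_codes(landcover, scheme)
    return _binary_from_codes(landcover, scheme.green_codes)


def classify_natural(landcover: Grid, scheme: LandcoverScheme | None = None) -> Grid:
    """Binary natural-space mask: greenspace plus open water (blue space)."""
    scheme = scheme or LandcoverScheme()
    _check_codes(landcover, scheme)
    codes = np.append(scheme.green_codes, scheme.water_code)
    return _binary_from_codes(landcover, codes)
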