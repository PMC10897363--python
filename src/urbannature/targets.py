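"""City-level summaries and pass/fail evaluation of the two UND targets.

Quality Total Cover (QTC): 30-40% of city area should be greenspace;
evaluated against the city mean of the 100 m green fractions.  Equitable
Spatial Distribution (ESD): 70% of the population should live within a
15-minute walk of natural space; evaluated against the population-weighted
mean of the 100 m access fractions.  All comparisons are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grid import CityMask, Grid, masked_cells

__all__ = ["CityMetrics", "TargetReport", "summarize_city", "evaluate_targets"]


@dataclass
class CityMetrics:
    """Aggregate exposure statistics over a city's 100 m cells."""

    mean_ndvi: float
    mean_natural_ndvi: float
    green_fraction: float
    natural_fraction: float
    access_fraction_area: float
    access_fraction_pop: float | None
    n_cells: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TargetReport:
    """Pass/fail flags against the two targets with the thresholds used."""

    qtc_pass_30: bool
    qtc_pass_40: bool
    esd_pass: bool | None
    qtc_range: tuple[float, float] = (0.30, 0.40)
    esd_threshold: float = 0.70

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qtc_range"] = list(self.qtc_range)
        return d


def _masked_mean(grid: Grid, mask: CityMask) -> float:
    vals = masked_cells(grid, mask)
    if vals.size == 0:
        raise ValueError("city mask selects no valid cells")
    return float(np.mean(vals))


def summarize_city(
    ndvi_100m: Grid,
    natural_ndvi_100m: Grid,
    green_frac_100m: Grid,
    natural_frac_100m: Grid,
    access_frac_100m: Grid,
    pop_100m: Grid | None,
    mask: CityMask,
) -> CityMetrics:
    """Unweighted and population-weighted city means over masked 100 m cells.

    The population-weighted access share is sum(pop * access) / sum(pop)
    over city cells; with no population raster, or zero total population,
    it is reported missing rather than guessed.  Zero-population cells
    still count toward the plain area means.
    """
    metrics = CityMetrics(
        mean_ndvi=_masked_mean(ndvi_100m, mask),
        mean_natural_ndvi=_masked_mean(natural_ndvi_100m, mask),
        green_fraction=_masked_mean(green_frac_100m, mask),
        natural_fraction=_masked_mean(natural_frac_100m, mask),
        access_fraction_area=_masked_mean(access_frac_100m, mask),
        access_fraction_pop=None,
        n_cells=int(
            (mask.bool_array() & green_frac_100m.valid_mask()).sum()
        ),
    )
    if pop_100m is not None:
        access_frac_100m.require_aligned(pop_100m, "access and population grids")
        inside = mask.bool_array() & access_frac_100m.valid_mask() & pop_100m.valid_mask()
        pop = pop_100m.values[inside].astype(np.float64)
        acc = access_frac_100m.values[inside].astype(np.float64)
        total = pop.sum()
        if total > 0:
            metrics.access_fraction_pop = float(np.dot(pop, acc) / total)
    return metrics


def evaluate_targets(
    metrics: CityMetrics,
    qtc_range: tuple[float, float] = (0.30, 0.40),
    esd_threshold: float = 0.70,
) -> TargetReport:
    """Inclusive threshold comparisons of city metrics against both targets."""
    esd = None
    if metrics.access_fraction_pop is not None:
        esd = bool(metrics.access_fraction_pop >= esd_threshold)
    return TargetReport(
        qtc_pass_30=bool(metrics.green_fraction >= qtc_range[0]),
        qtc_pass_40=bool(metrics.green_fraction >= qtc_range[1]),
        esd_pass=esd,
        qtc_range=qtc_range,
        esd_threshold=esd_threshold,
    )
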