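"""End-to-end orchestration: layers in, city report out.

Mirrors the three analysis stages: (1) build the greenest-pixel NDVI
composite and the binary landcover masks at 10 m; (2) aggregate to 100 m
and relate the landcover and NDVI views of the city by per-cell OLS;
(3) score the city against the Quality Total Cover and Equitable Spatial
Distribution targets and convert both targets to the NDVI scale.

Inputs come either from GeoTIFF paths or from a synthetic-city recipe.
Intermediate rasters (composite, binary masks, access layers, 100 m
aggregates) are written for inspection, and the result is a JSON/CSV
report that is byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import access_fraction_100m, buffer_access, filter_small_patches
from .grid import CityMask, Grid, block_aggregate, read_raster, write_raster
from .landcover import LandcoverScheme, classify_green, classify_natural
from .ndvi import BandPair, compute_ndvi, fuse_natural_ndvi, greenest_composite, threshold_natural
from .regress import (
    ConversionResult,
    DegeneratePredictorError,
    convert_esd,
    convert_qtc,
)
from .simulate import CityBundle, CityRecipe, generate_city
from .targets import CityMetrics, TargetReport, evaluate_targets, summarize_city

__all__ = ["RunConfig", "InputPaths", "CityReport", "run_pipeline"]

log = logging.getLogger("urbannature")


@dataclass(frozen=True)
class InputPaths:
    """GeoTIFF inputs for one city (all on a common projected grid)."""

    landcover: str
    bands: tuple[tuple[str, str], ...]  # (nir, vis) per date
    mask: str
    population: str | None = None
    mask_100m: str | None = None  # derived from `mask` when absent


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``paths`` / ``recipe`` must be given.  Thresholds
    default to the target definitions: 0.5 ha minimum patch, 1,000 m
    walking buffer, QTC range 0.30-0.40, ESD level 0.70, and the 75%
    green-area level for the NDVI threshold.
    """

    paths: InputPaths | None = None
    recipe: CityRecipe | None = None
    output_dir: str = "out"
    min_patch_area_m2: float = 5000.0
    buffer_radius_m: float = 1000.0
    qtc_range: tuple[float, float] = (0.30, 0.40)
    esd_threshold: float = 0.70
    threshold_level: float = 0.75  # green-area level defining the NDVI threshold
    connectivity: int = 8
    qtc_response: str = "ndvi"
    esd_response: str = "ndvi_access"
    write_intermediates: bool = True

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.recipe is None):
            raise ValueError("exactly one of paths or recipe must be set")
        if self.threshold_level not in (0.75, 0.90, 1.00):
            raise ValueError("threshold_level must be one of 0.75, 0.90, 1.00")
        if not 0 < self.qtc_range[0] <= self.qtc_range[1] <= 1:
            raise ValueError("qtc_range must be increasing within (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def canonical_dict(self) -> dict:
        """Config as plain JSON, without the output location (which has no
        bearing on the results and would break run-to-run comparability)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        d.pop("write_intermediates", None)
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CityReport:
    """Metrics, target verdicts, conversions, and provenance for one city."""

    metrics: CityMetrics
    targets: TargetReport
    conversion: ConversionResult | None
    conversion_error: str | None
    ndvi_threshold: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "targets": self.targets.to_dict(),
            "conversion": self.conversion.to_dict() if self.conversion else None,
            "conversion_error": self.conversion_error,
            "ndvi_threshold": self.ndvi_threshold,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_csv_row(self) -> pd.DataFrame:
        flat: dict = {}
        flat.update(self.metrics.to_dict())
        t = self.targets.to_dict()
        flat.update({k: t[k] for k in ("qtc_pass_30", "qtc_pass_40", "esd_pass")})
        if self.conversion is not None:
            q = self.conversion.qtc
            flat["ndvi_at_30"] = q.predictions[0.30]
            flat["ndvi_at_40"] = q.predictions[0.40]
            flat["qtc_r2"] = q.fit.r2
            flat["qtc_rmse"] = q.fit.rmse
            if self.conversion.esd is not None:
                flat["esd_at_70"] = self.conversion.esd.at_70
                flat["esd_r2"] = self.conversion.esd.fit.r2
                flat["esd_rmse"] = self.conversion.esd.fit.rmse
        flat["ndvi_threshold"] = self.ndvi_threshold
        return pd.DataFrame([flat])


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: RunConfig) -> tuple[Grid, list[BandPair], Grid | None, CityMask, CityMask]:
    if config.recipe is not None:
        bundle = generate_city(config.recipe)
        return (
            bundle.landcover,
            bundle.band_pairs(),
            bundle.population,
            bundle.mask10,
            bundle.mask100,
        )
    paths = config.paths
    landcover = read_raster(paths.landcover)
    bands = [
        BandPair(nir=read_raster(nir), vis=read_raster(vis), date_tag=f"date{i:02d}")
        for i, (nir, vis) in enumerate(paths.bands)
    ]
    mask10 = CityMask(read_raster(paths.mask))
    if paths.mask_100m is not None:
        mask100 = CityMask(read_raster(paths.mask_100m))
    else:
        frac = block_aggregate(mask10.grid, 10, "mean")
        vals = np.where(frac.valid_mask(), (frac.values >= 0.5), 0).astype(np.uint8)
        mask100 = CityMask(frac.with_values(vals))
    population = read_raster(paths.population) if paths.population else None
    return landcover, bands, population, mask10, mask100


def _maybe_write(config: RunConfig, name: str, grid: Grid) -> None:
    if not config.write_intermediates:
        return
    out = Path(config.output_dir)
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        grid = grid.with_values(vals.astype(np.float32), nodata=grid.nodata)
    write_raster(grid, out / f"{name}.tif")


def run_pipeline(config: RunConfig) -> CityReport:
    """Execute all stages and write ``report.json`` / ``report.csv``.

    Any stage failure is re-raised as :class:`StageError` naming the
    stage; intermediates written up to that point are left on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = LandcoverScheme()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %-22s done in %6.2f s", name, time.perf_counter() - t0)
            return result
        return deco

    @stage("load_inputs")
    def inputs():
        return _load_inputs(config)

    landcover, bands, population, mask10, mask100 = inputs

    @stage("ndvi_composite")
    def composite():
        layers = [compute_ndvi(bp) for bp in bands]
        comp = greenest_composite(layers)
        _maybe_write(config, "ndvi_composite", comp)
        return comp

    @stage("classify")
    def binaries():
        green10 = classify_green(landcover, scheme)
        natural10 = classify_natural(landcover, scheme)
        _maybe_write(config, "green_10m", green10)
        _maybe_write(config, "natural_10m", natural10)
        return green10, natural10

    green10, natural10 = binaries

    @stage("fuse_natural_ndvi")
    def fused():
        f = fuse_natural_ndvi(composite, landcover, scheme)
        _maybe_write(config, "natural_ndvi", f)
        return f

    @stage("aggregate_100m")
    def aggregates():
        agg = {
            "ndvi_100m": block_aggregate(composite, 10, "mean"),
            "natural_ndvi_100m": block_aggregate(fused, 10, "mean"),
            "green_frac_100m": block_aggregate(green10, 10, "mean"),
            "natural_frac_100m": block_aggregate(natural10, 10, "mean"),
        }
        for name, grid in agg.items():
            _maybe_write(config, name, grid)
        return agg

    @stage("landcover_access")
    def lc_access():
        filtered = filter_small_patches(
            natural10, config.min_patch_area_m2, connectivity=config.connectivity
        )
        flags = buffer_access(filtered, config.buffer_radius_m, config.min_patch_area_m2)
        frac = access_fraction_100m(flags)
        _maybe_write(config, "lc_access_10m", flags)
        _maybe_write(config, "lc_access_100m", frac)
        return frac

    @stage("summarize_city")
    def metrics():
        return summarize_city(
            aggregates["ndvi_100m"],
            aggregates["natural_ndvi_100m"],
            aggregates["green_frac_100m"],
            aggregates["natural_frac_100m"],
            lc_access,
            population,
            mask100,
        )

    @stage("evaluate_targets")
    def verdicts():
        return evaluate_targets(metrics, config.qtc_range, config.esd_threshold)

    conversion: ConversionResult | None = None
    conversion_error: str | None = None
    ndvi_threshold: float | None = None
    qtc = None
    try:
        @stage("convert_qtc")
        def qtc_result():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # out-of-range predictions kept as-is
                return convert_qtc(
                    aggregates["green_frac_100m"],
                    aggregates["ndvi_100m"],
                    mask100,
                    response=config.qtc_response,
                )
        qtc = qtc_result
    except StageError as err:
        if isinstance(err.cause, DegeneratePredictorError):
            conversion_error = str(err.cause)
            log.warning("QTC conversion skipped: %s", conversion_error)
        else:
            raise

    if qtc is not None:
        esd = None
        try:
            @stage("convert_esd")
            def esd_result():
                t = float(np.clip(qtc.threshold(config.threshold_level), -1.0, 1.0))
                natural_t = threshold_natural(fused, t)
                filtered_t = filter_small_patches(
                    natural_t, config.min_patch_area_m2,
                    connectivity=config.connectivity,
                )
                flags_t = buffer_access(
                    filtered_t, config.buffer_radius_m, config.min_patch_area_m2
                )
                frac_t = access_fraction_100m(flags_t)
                _maybe_write(config, "ndvi_access_10m", flags_t)
                _maybe_write(config, "ndvi_access_100m", frac_t)
                return t, convert_esd(
                    lc_access, frac_t, mask100, at=config.esd_threshold,
                    response=config.esd_response,
                )
            ndvi_threshold, esd = esd_result
        except StageError as err:
            if isinstance(err.cause, DegeneratePredictorError):
                conversion_error = str(err.cause)
                log.warning("ESD conversion skipped: %s", conversion_error)
            else:
                raise
        conversion = ConversionResult(
            qtc=qtc, esd=esd, threshold_level=config.threshold_level
        )

    provenance = {
        "package": "urbannature",
        "version": __version__,
        "config_hash": RunConfig.config_hash(config),
        "seed": config.recipe.seed if config.recipe is not None else None,
        "config": config.canonical_dict(),
    }
    report = CityReport(
        metrics=metrics,
        targets=verdicts,
        conversion=conversion,
        conversion_error=conversion_error,
        ndvi_threshold=ndvi_threshold,
        provenance=provenance,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    report.to_csv_row().to_csv(out / "report.csv", index=False)
    return report
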