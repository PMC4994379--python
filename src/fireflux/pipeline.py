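"""End-to-end orchestration: simulate -> map burns -> fit loss -> emissions
-> Monte Carlo -> regional scaling -> report.

Every stage reads and writes standard files (TIFF rasters, CSV tables,
GeoJSON points) inside one output directory, logs what it produced, and is
individually re-runnable. A single global seed fans out to fixed per-stage
substreams, so a full run is deterministic and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .burnmap import DEFAULT_ENDMEMBERS, map_burn_scars
from .emissions import (
    EmissionConfig,
    EmissionSummary,
    compute_class_emissions,
    npcc_ratio,
    percent_burned,
    records_from_frame,
    records_to_frame,
    summarize,
)
from .grids import BurnScarMap, Raster
from .lossmodel import apply_loss, fit_york, model_report, write_plot_pairs
from .montecarlo import McConfig, McResult, run_mc, summary_to_csv
from .scaling import (
    count_by_class_month,
    filter_fires,
    fit_wls,
    forest_polygon_samples,
    predict_area,
    scale_emissions,
    write_fires_csv,
    write_fires_geojson,
)
from .synthetic import LandscapeConfig, generate_plot_pairs, generate_scene

log = logging.getLogger("fireflux")

STAGES = ("simulate", "map_burns", "fit_loss", "emissions", "mc", "scale", "report")


@dataclass
class PipelineConfig:
    """Nested stage configuration with one global seed."""

    out_dir: Path = Path("fireflux_out")
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    n_plot_pairs: int = 50
    plot_x_error_sd: float = 15.0
    plot_y_error_sd: float = 15.0
    mc: McConfig = field(default_factory=McConfig)
    emission: EmissionConfig = field(default_factory=EmissionConfig)
    wls_groups: int = 5
    regional_fire_count: float = reference.BLA_FOREST_FIRE_COUNT

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.landscape.seed = self.seed
        self.mc.seed = self.seed
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("out_dir", "seed", "n_plot_pairs", "plot_x_error_sd",
                    "plot_y_error_sd", "wls_groups", "regional_fire_count"):
            if key in doc:
                kwargs[key] = doc[key]
        if "stages" in doc:
            kwargs["stages"] = {s: bool(doc["stages"].get(s, True)) for s in STAGES}
        if "landscape" in doc:
            kwargs["landscape"] = LandscapeConfig(**doc["landscape"])
        if "mc" in doc:
            kwargs["mc"] = McConfig(**doc["mc"])
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_artifact(path: Path) -> None:
    log.info("wrote %s (sha256 %s)", path, _checksum(path))


@dataclass
class PipelineResult:
    records: list | None = None
    summary: EmissionSummary | None = None
    mc_result: McResult | None = None
    scaling: dict | None = None
    loss_model: object = None


def validate_stage_inputs(cfg: PipelineConfig) -> None:
    """Before running anything, check that each enabled stage's inputs exist
    or are produced by an enabled upstream stage."""
    out = cfg.out_dir
    needs = {
        "map_burns": [out / f"reflectance_m{m:02d}.tif" for m in (6, 7, 8, 9, 10)],
        "fit_loss": [out / "plot_pairs.csv"],
        "emissions": [out / "landcover.tif", out / "biomass.tif", out / "burns.tif"],
        "mc": [out / "landcover.tif", out / "biomass.tif",
               out / "biomass_error.tif", out / "burns.tif"],
        "scale": [out / "fires.csv", out / "burns.tif", out / "landcover.tif"],
        "report": [out / "emission_table.csv"],
    }
    upstream = {
        "map_burns": "simulate", "fit_loss": "simulate", "emissions": "simulate",
        "mc": "simulate", "scale": "simulate", "report": "emissions",
    }
    # map_burns also feeds burns.tif when simulate is off
    for stage, paths in needs.items():
        if not cfg.stages.get(stage, False):
            continue
        up = upstream[stage]
        if cfg.stages.get(up, False):
            continue
        missing = [p for p in paths if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"stage '{stage}': missing inputs {', '.join(str(m) for m in missing)} "
                f"and upstream stage '{up}' is disabled"
            )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all enabled stages in dependency order."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    validate_stage_inputs(cfg)
    result = PipelineResult()
    scene = None

    if cfg.stages.get("simulate", False):
        log.info("stage simulate: %dx%d grid, seed %d",
                 cfg.landscape.grid_rows, cfg.landscape.grid_cols, cfg.seed)
        scene = generate_scene(cfg.landscape)
        scene.landcover.write(out / "landcover.tif")
        scene.biomass.write(out / "biomass.tif")
        scene.biomass_error.write(out / "biomass_error.tif")
        scene.truth_burn.write(out / "truth_burns.tif")
        for month, refl in scene.reflectance_by_month:
            refl.write(out / f"reflectance_m{month:02d}.tif")
        write_fires_csv(scene.fires, out / "fires.csv")
        write_fires_geojson(scene.fires, out / "fires.geojson")
        pairs = generate_plot_pairs(
            cfg.n_plot_pairs,
            x_error_sd=cfg.plot_x_error_sd,
            y_error_sd=cfg.plot_y_error_sd,
            seed=cfg.seed,
        )
        write_plot_pairs(pairs, out / "plot_pairs.csv")
        for p in ("landcover.tif", "biomass.tif", "truth_burns.tif",
                  "fires.csv", "plot_pairs.csv"):
            _log_artifact(out / p)

    if cfg.stages.get("map_burns", False):
        log.info("stage map_burns")
        images = [
            (m, Raster.read(out / f"reflectance_m{m:02d}.tif")) for m in (6, 7, 8, 9, 10)
        ]
        burn = map_burn_scars(images, endmembers=DEFAULT_ENDMEMBERS)
        burn.write(out / "burns.tif")
        _log_artifact(out / "burns.tif")

    if cfg.stages.get("fit_loss", False):
        log.info("stage fit_loss")
        from .lossmodel import read_plot_pairs

        pairs = read_plot_pairs(out / "plot_pairs.csv")
        model = fit_york(pairs)
        result.loss_model = model
        (out / "loss_model.txt").write_text(model_report(model))
        _log_artifact(out / "loss_model.txt")
    else:
        from .lossmodel import LossModel

        result.loss_model = LossModel(reference.LOSS_SLOPE, reference.LOSS_SLOPE_SD)

    landcover = biomass = burn = None
    if cfg.stages.get("emissions", False):
        log.info("stage emissions")
        landcover = Raster.read(out / "landcover.tif")
        biomass = Raster.read(out / "biomass.tif")
        burn = BurnScarMap.read(out / "burns.tif")
        _, loss = apply_loss(biomass, result.loss_model, burn)
        records = compute_class_emissions(loss, landcover, burn, cfg.emission,
                                          biomass=biomass)
        result.records = records
        if scene is not None:
            areas = scene.class_areas_km2()
        else:
            px_km2 = landcover.pixel_area_ha / 100.0
            codes, counts = np.unique(landcover.data, return_counts=True)
            areas = {int(c): float(n) * px_km2 for c, n in zip(codes, counts)}
        result.summary = summarize(records, class_areas_km2=areas)
        records_to_frame(records).to_csv(out / "emission_table.csv")
        burned_table = pd.DataFrame(
            {
                "class_code": [r.class_code for r in records],
                "name": [r.name for r in records],
                "area_km2": [areas.get(r.class_code, 0.0) for r in records],
                "burned_km2": [r.burned_area_km2 for r in records],
                "percent_burned": [
                    percent_burned(r.burned_area_km2, areas[r.class_code])
                    if areas.get(r.class_code) else 0.0
                    for r in records
                ],
            }
        ).set_index("class_code")
        burned_table.to_csv(out / "burned_area_table.csv")
        _log_artifact(out / "emission_table.csv")
        _log_artifact(out / "burned_area_table.csv")

    if cfg.stages.get("mc", False):
        log.info("stage mc: %d repetitions", cfg.mc.n_reps)
        landcover = landcover or Raster.read(out / "landcover.tif")
        biomass = biomass or Raster.read(out / "biomass.tif")
        biomass_error = Raster.read(out / "biomass_error.tif")
        burn = burn or BurnScarMap.read(out / "burns.tif")
        result.mc_result = run_mc(landcover, biomass, biomass_error, burn,
                                  result.loss_model, cfg.mc, cfg.emission)
        trace = result.mc_result.trace.copy()
        trace.columns = [f"{c}_{m}" for c, m in trace.columns]
        trace.to_csv(out / "mc_trace.csv")
        summary_to_csv(result.mc_result, out / "mc_summary.csv")
        _log_artifact(out / "mc_summary.csv")

    if cfg.stages.get("scale", False):
        log.info("stage scale")
        from .scaling import read_fires_csv

        landcover = landcover or Raster.read(out / "landcover.tif")
        burn = burn or BurnScarMap.read(out / "burns.tif")
        fires = read_fires_csv(out / "fires.csv")
        kept = filter_fires(fires, burn)
        write_fires_csv(kept, out / "fires_filtered.csv")
        count_by_class_month(kept, landcover).to_csv(out / "fire_counts.csv")
        samples = forest_polygon_samples(burn, landcover, kept)
        scaling: dict = {"n_polygons": int(len(samples))}
        if len(samples) >= 2 * cfg.wls_groups:
            model = fit_wls(samples, n_groups=cfg.wls_groups)
            area, interval = predict_area(model, cfg.regional_fire_count)
            forest_b = reference.class_table().loc[1, "biomass_mean"]
            scaled = scale_emissions(area, forest_b, alpha=result.loss_model.alpha)
            scaling.update(
                slope_ha_per_fire=model.slope,
                intercept_ha=model.intercept,
                extrapolated_area_ha=area,
                area_interval_ha=interval,
                gross_c_tg=scaled.gross_c_tg,
                total_c_tg=scaled.total_c_tg,
            )
            pd.DataFrame([scaling]).to_csv(out / "scaling_summary.csv", index=False)
            _log_artifact(out / "scaling_summary.csv")
        else:
            log.warning("scale: only %d forest polygons, skipping WLS", len(samples))
        result.scaling = scaling

    if cfg.stages.get("report", False):
        write_report(result, cfg, out)

    return result


def write_report(result: PipelineResult, cfg: PipelineConfig, out: Path) -> None:
    """Human-readable run summary next to the machine-readable CSVs."""
    lines = ["fireflux run report", "=" * 40]
    records = result.records
    if records is None and (out / "emission_table.csv").exists():
        records = records_from_frame(pd.read_csv(out / "emission_table.csv",
                                                 index_col="class_code"))
    if records:
        s = result.summary or summarize(records)
        lines += [
            f"burned area            : {sum(r.burned_area_km2 for r in records):,.1f} km^2",
            f"total carbon loss      : {s.total_c_tg:.3f} Tg C",
            f"gross emission (year)  : {s.gross_c_tg:.3f} Tg C",
            f"committed emission     : {s.committed_c_tg:.3f} Tg C",
            f"intact-vegetation loss : {s.intact_total_tg:.3f} Tg C",
            f"RR gross subtotal      : {s.rr_gross_tg:.3f} Tg C",
            f"LTR gross subtotal     : {s.ltr_gross_tg:.3f} Tg C",
            f"share of annual target : {npcc_ratio(s.total_c_tg, cfg.emission):.1f} %",
        ]
    if result.mc_result is not None:
        lines += [
            f"MC total carbon loss   : {result.mc_result.total_mean():.3f} "
            f"+- {result.mc_result.total_sd():.3f} Tg C",
        ]
    if result.scaling and "extrapolated_area_ha" in result.scaling:
        lines += [
            f"extrapolated forest burned area : "
            f"{result.scaling['extrapolated_area_ha']:,.0f} ha",
            f"extrapolated forest gross C     : "
            f"{result.scaling['gross_c_tg']:.3f} Tg",
        ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    _log_artifact(out / "report.txt")
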