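"""End-to-end pipeline: simulate -> extract -> fit -> index -> map -> validate.

``PipelineConfig`` gathers every knob (paths or a synthetic-city
configuration, buffer radius, working/mapping resolutions, model choice,
normalisation and building-statistics modes) and round-trips through YAML.
``run_pipeline`` executes the stages, logging per-stage sample sizes and
output hashes so a run is fully reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .env_features import (PCTILE_COLUMNS, PercentileNormalizer,
                           binarize_landuse, extract_cohort_features,
                           moving_window_features)
from .raster import RasterLayer
from .risk_models import (LogisticModelSpec, adjusted_ors, fit_logistic_irls)
from .synthetic_city import (CityConfig, generate_cohort, generate_rasters,
                             generate_tpu_grid, inject_missing,
                             simulate_outcomes)
from .tpu import TPUGrid
from .validation import extract_at_points, validate_index
from .vuln_index import (IndexWeights, VulnRaster, aggregate_to_tpu,
                         compute_index_raster, derive_weights)

logger = logging.getLogger("geovuln")

__all__ = ["PipelineConfig", "run_pipeline", "run_synthetic_replicate",
           "build_index_surface", "MAPPABLE_KINDS"]

#: variables the mapping stage has an area-level layer for
MAPPABLE_KINDS = {
    "low_education": "binary-population-percentage",
    "pct_residential": "continuous-percentage",
    "pct_vegetation": "continuous-percentage",
    "avg_build_height_pctile": "continuous-percentage",
    "std_build_height_pctile": "continuous-percentage",
}


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    # inputs: either file paths ...
    land_use_path: str | None = None
    vegetation_path: str | None = None
    building_height_path: str | None = None
    cohort_path: str | None = None
    tpu_path: str | None = None
    # ... or a synthetic city
    simulate: bool = True
    city: dict = field(default_factory=dict)   # CityConfig overrides
    seed: int = 0
    # analysis knobs
    radius_m: float = 400.0
    working_resolution_m: float | None = None  # None: native grid
    mapping_resolution_m: float | None = None
    model_id: int = 3
    built_cells_only: bool = True
    normalization: str = "cohort"              # subject percentiles: cohort | citywide
    rounded_weights: bool = True
    out_dir: str = "geovuln_out"

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def city_config(self) -> CityConfig:
        return CityConfig(seed=self.seed, **self.city)


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def build_index_surface(weights: IndexWeights, land_use: RasterLayer,
                        vegetation: RasterLayer, building_height: RasterLayer,
                        tpus: TPUGrid, radius_m: float = 400.0,
                        built_cells_only: bool = True) -> VulnRaster:
    """Mapping-stage layers + weighted sum.

    Environmental layers are 400-m moving-window summaries at the mapping
    resolution (the same buffer operator as for subjects); height layers are
    percentile-normalised citywide; pct. low education is rasterized
    zone-constant from the TPU census attribute.  Cells with no building in
    the window are nodata (unsettled areas stay blank).
    """
    residential = binarize_landuse(land_use)
    win = moving_window_features(residential, vegetation, building_height,
                                 radius_m=radius_m,
                                 built_cells_only=built_cells_only)
    layers = {
        "pct_residential": win["pct_residential"],
        "pct_vegetation": win["pct_vegetation"],
        "pct_low_education": tpus.rasterize_attribute(residential),
    }
    for raw, pct in zip(["avg_build_height_m", "std_build_height_m"], PCTILE_COLUMNS):
        src = win[raw]
        vals = np.full(src.shape, np.nan)
        ok = src.valid_mask()
        if ok.any():
            norm = PercentileNormalizer().fit(src.values[ok])
            vals[ok] = norm.transform(src.values[ok])
        layers[pct] = RasterLayer(values=vals, origin=src.origin,
                                  resolution_m=src.resolution_m, nodata=src.nodata)
    return compute_index_raster(weights, layers)


def run_synthetic_replicate(config: CityConfig, build_index: bool = True,
                            cell_approx: bool = False,
                            working_resolution_m: float | None = None,
                            radius_m: float = 400.0) -> dict:
    """One synthetic city end to end; returns all stage products.

    Keys: land_use, residential, vegetation, building_height, tpus, cohort,
    features, data (cohort+features), fit3, and with ``build_index`` also
    weights (unrounded), vuln, tpu_summary, validation.
    """
    land_use, veg, bh = generate_rasters(config)
    tpus = generate_tpu_grid(config)
    residential = binarize_landuse(land_use)
    cohort = generate_cohort(config, land_use, tpus=tpus)
    feats = extract_cohort_features(cohort, residential, veg, bh,
                                    radius_m=radius_m,
                                    working_resolution_m=working_resolution_m,
                                    cell_approx=cell_approx)
    cohort = simulate_outcomes(cohort, feats, config)
    data = pd.concat([cohort, feats], axis=1)
    out = dict(land_use=land_use, residential=residential, vegetation=veg,
               building_height=bh, tpus=tpus, cohort=cohort, features=feats,
               data=data)
    out["fit3"] = fit_logistic_irls(LogisticModelSpec(model_id=3), data)
    if build_index:
        ors = adjusted_ors(out["fit3"])
        weights = derive_weights(ors, kinds=MAPPABLE_KINDS, round_dp=None)
        vuln = build_index_surface(weights, land_use, veg, bh, tpus,
                                   radius_m=radius_m)
        idx = extract_at_points(vuln, data[["x", "y"]].to_numpy())
        out["weights"] = weights
        out["vuln"] = vuln
        out["tpu_summary"] = aggregate_to_tpu(vuln, tpus)
        out["validation"] = validate_index(idx, data["case"])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage per the configuration; returns results + run log.

    Stage failures raise with the stage name; the log records inputs,
    parameters, sample sizes (geocoded, complete-case, cases/controls) and
    output hashes.
    """
    from . import io as gio

    log: dict = {"config": asdict(config), "stages": {}}
    results: dict = {"log": log}
    stage = "load"
    try:
        if config.simulate:
            stage = "simulate"
            city = config.city_config()
            land_use, veg, bh = generate_rasters(city)
            tpus = generate_tpu_grid(city)
            cohort = generate_cohort(city, land_use, tpus=tpus)
        else:
            layers = {
                "land_use": gio.read_ascii_grid(config.land_use_path),
                "vegetation": gio.read_ascii_grid(config.vegetation_path),
                "building_height": gio.read_ascii_grid(config.building_height_path),
            }
            gio.check_coregistered(layers)
            land_use, veg, bh = (layers["land_use"], layers["vegetation"],
                                 layers["building_height"])
            tpus = gio.read_tpu_geojson(config.tpu_path)
            cohort = gio.read_cohort_csv(config.cohort_path,
                                         require_outcome=True)
            city = None

        stage = "extract"
        residential = binarize_landuse(land_use)
        feats = extract_cohort_features(
            cohort, residential, veg, bh, radius_m=config.radius_m,
            working_resolution_m=config.working_resolution_m,
            built_cells_only=config.built_cells_only)

        if config.simulate:
            stage = "outcomes"
            cohort = simulate_outcomes(cohort, feats, city)
            if city.missing_rate > 0:
                cohort = inject_missing(cohort, city)
                if "gds15" in cohort.columns:
                    case = (cohort["gds15"] >= 8).astype(float)
                    case[cohort["gds15"].isna()] = np.nan
                    cohort["case"] = case
        data = pd.concat([cohort.reset_index(drop=True),
                          feats.reset_index(drop=True)], axis=1)
        n_cases = int((data["case"] == 1).sum())
        n_controls = int((data["case"] == 0).sum())
        log["stages"]["extract"] = {
            "n_geocoded": len(data), "n_cases": n_cases, "n_controls": n_controls,
            "features_hash": _sha(feats[["pct_residential", "pct_vegetation"]].to_numpy()),
        }
        logger.info("extract: n=%d cases=%d controls=%d", len(data), n_cases, n_controls)

        stage = "fit"
        fits = {m: fit_logistic_irls(LogisticModelSpec(model_id=m), data)
                for m in (1, 2, 3)}
        log["stages"]["fit"] = {
            f"model{m}": {"n_used": f.n_used, "n_removed": f.n_removed,
                          "converged": f.converged, "loglik": f.loglik}
            for m, f in fits.items()
        }

        stage = "weights"
        ors3 = adjusted_ors(fits[config.model_id])
        weights = derive_weights(ors3, kinds=MAPPABLE_KINDS,
                                 round_dp=2 if config.rounded_weights else None)
        log["stages"]["weights"] = {"weights": dict(weights.weights)}

        stage = "map"
        map_lu, map_veg, map_bh = land_use, veg, bh
        vuln = build_index_surface(weights, map_lu, map_veg, map_bh, tpus,
                                   radius_m=config.radius_m,
                                   built_cells_only=config.built_cells_only)
        summary = aggregate_to_tpu(vuln, tpus)
        ok = vuln.layer.valid_mask()
        log["stages"]["map"] = {
            "index_min": float(np.nanmin(vuln.layer.values)),
            "index_max": float(np.nanmax(vuln.layer.values)),
            "n_valid_cells": int(ok.sum()),
            "raster_hash": _sha(np.nan_to_num(vuln.layer.values)),
        }

        stage = "validate"
        idx = extract_at_points(vuln, data[["x", "y"]].to_numpy())
        ok_case = data["case"].notna().to_numpy()
        report = validate_index(idx[ok_case], data.loc[ok_case, "case"].to_numpy())
        log["stages"]["validate"] = {
            "or_per_0.1": report.or_per_scale_unit.or_point,
            "ci": [report.or_per_scale_unit.ci_low, report.or_per_scale_unit.ci_high],
            "n_subjects": report.n_subjects,
            "n_excluded_nodata": report.n_excluded_nodata,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    results.update(dict(land_use=land_use, vegetation=veg, building_height=bh,
                        tpus=tpus, cohort=cohort, features=feats, data=data,
                        fits=fits, ors3=ors3, weights=weights, vuln=vuln,
                        tpu_summary=summary, validation=report))

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        gio.write_ascii_grid(vuln.layer, out_dir / "vuln_index.asc")
        gio.write_cohort_csv(data, out_dir / "cohort_features.csv")
        gio.write_tpu_geojson(tpus, out_dir / "tpu_index.geojson", summary=summary)
        (out_dir / "fit.json").write_text(json.dumps(_fits_json(fits), indent=1))
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return results


def _fits_json(fits) -> dict:
    out = {}
    for m, f in fits.items():
        ors = adjusted_ors(f) if f.converged else {}
        out[f"model{m}"] = {
            "terms": f.terms,
            "beta": [float(b) for b in f.beta],
            "se": [float(s) for s in f.se],
            "converged": f.converged, "n_used": f.n_used,
            "loglik": f.loglik,
            "ors": {t: {"or": r.or_point, "ci": [r.ci_low, r.ci_high],
                        "significant": r.significant} for t, r in ors.items()},
        }
    return out
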