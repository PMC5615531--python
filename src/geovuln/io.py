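"""File formats: ESRI ASCII grid rasters, cohort CSV, TPU GeoJSON, YAML config.

Rasters travel as single-band ESRI ASCII grids (plain text, ``.asc``) whose
header carries the registration (ncols/nrows/xllcorner/yllcorner/cellsize)
and nodata sentinel; categorical layers get a ``<path>.classes.json``
side-car with the integer-code -> label mapping.  All readers/writers
round-trip values, registration and nodata exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .raster import RasterLayer
from .tpu import TPUGrid, TPUZone

__all__ = [
    "write_ascii_grid", "read_ascii_grid",
    "write_cohort_csv", "read_cohort_csv",
    "write_tpu_geojson", "read_tpu_geojson",
    "check_coregistered",
]

COHORT_REQUIRED = ["subject_id", "x", "y", "older_ages", "male", "not_married",
                   "low_education", "living_alone", "dementia", "physical_activity",
                   "cardiovascular", "respiratory", "alcohol", "smoking", "gds15"]


# -- rasters ----------------------------------------------------------------

def write_ascii_grid(layer: RasterLayer, path) -> Path:
    path = Path(path)
    nrows, ncols = layer.shape
    vals = layer.values.copy()
    nodata = layer.nodata if np.isfinite(layer.nodata) else -9999.0
    vals[~np.isfinite(vals)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {layer.origin[0]!r}\nyllcorner {layer.origin[1]!r}\n"
                 f"cellsize {layer.resolution_m!r}\nNODATA_value {nodata!r}\n")
        # ASCII grid rows run north -> south; in memory row 0 is southernmost
        np.savetxt(fh, vals[::-1], fmt="%.10g")
    if layer.categories:
        side = path.with_name(path.name + ".classes.json")
        side.write_text(json.dumps({str(k): v for k, v in layer.categories.items()},
                                   indent=1))
    return path


def read_ascii_grid(path) -> RasterLayer:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1].copy()
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    categories = None
    side = path.with_name(path.name + ".classes.json")
    if side.exists():
        categories = {int(k): v for k, v in json.loads(side.read_text()).items()}
    return RasterLayer(values=values,
                       origin=(header["xllcorner"], header["yllcorner"]),
                       resolution_m=header["cellsize"],
                       nodata=header.get("nodata_value", -9999.0),
                       categories=categories)


def check_coregistered(layers: dict[str, RasterLayer]) -> None:
    """Raise before any computation if layers disagree on grid registration."""
    names = list(layers)
    first = layers[names[0]]
    bad = [n for n in names[1:] if not first.is_coregistered(layers[n])]
    if bad:
        raise ValueError(f"layers not co-registered with '{names[0]}': {bad}")


# -- cohort -----------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path, require_outcome: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = COHORT_REQUIRED if require_outcome else COHORT_REQUIRED[:-1]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {missing}")
    bad_rows = df.index[df["gds15"].notna() & ~df["gds15"].between(0, 15)].tolist() \
        if "gds15" in df.columns else []
    if bad_rows:
        # +2: header line plus 1-based row numbering
        raise ValueError("gds15 outside [0, 15] at CSV lines "
                         f"{[i + 2 for i in bad_rows]}")
    if "case" not in df.columns and "gds15" in df.columns:
        df["case"] = (df["gds15"] >= 8).astype(float)
        df.loc[df["gds15"].isna(), "case"] = np.nan
    return df


# -- planning units ---------------------------------------------------------

def write_tpu_geojson(tpus: TPUGrid, path,
                      summary: pd.DataFrame | None = None) -> Path:
    """TPU polygons with census attributes; optionally joined index summary."""
    path = Path(path)
    by_id = summary.set_index("tpu_id") if summary is not None else None
    features = []
    for z in tpus.zones:
        props = {"tpu_id": z.tpu_id, "pct_low_education": z.pct_low_education}
        if by_id is not None and z.tpu_id in by_id.index:
            row = by_id.loc[z.tpu_id]
            props["index_mean"] = None if pd.isna(row["index_mean"]) else float(row["index_mean"])
            props["index_binned"] = None if pd.isna(row["index_binned"]) else float(row["index_binned"])
        features.append({"type": "Feature", "geometry": mapping(z.polygon),
                         "properties": props})
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_tpu_geojson(path) -> TPUGrid:
    data = json.loads(Path(path).read_text())
    zones = []
    for feat in data["features"]:
        geom = shape(feat["geometry"])
        props = feat["properties"]
        zones.append(TPUZone(tpu_id=int(props["tpu_id"]),
                             bounds=tuple(geom.bounds),
                             pct_low_education=float(props["pct_low_education"])))
    grid = TPUGrid(zones=zones)
    # overlap sanity check: zone areas should sum to the bounding extent
    xmin, ymin, xmax, ymax = grid.extent
    if grid.total_zone_area() > (xmax - xmin) * (ymax - ymin) * (1 + 1e-6):
        warnings.warn("TPU polygons overlap: zone areas exceed the grid extent")
    return grid
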