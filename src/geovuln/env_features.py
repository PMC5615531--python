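"""Built-environment exposure measures within circular buffers.

Four neighbourhood measures are computed for each subject from co-registered
raster layers, over a circular buffer (default radius 400 m) centred on the
subject's residential location:

* ``pct_residential`` — % of in-buffer cells classed residential (0–100);
* ``pct_vegetation`` — % vegetated (0–100);
* ``avg_build_height_m`` — mean building height over built cells (m);
* ``std_build_height_m`` — standard deviation of building height (m).

A cell belongs to the buffer iff its *centre* lies within the radius; the
buffer is clipped at the raster edge (the denominator counts only valid
in-extent cells).  Building statistics are computed over built cells only
(height > 0) by default; cells without buildings do not dilute the mean.
Height measures are subsequently rank-normalised to 0–100 percentiles across
the study sample before entering regression models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .raster import RasterLayer, resample_raster

__all__ = [
    "RESIDENTIAL_CLASSES",
    "BufferFeatureSet",
    "binarize_landuse",
    "buffer_features",
    "moving_window_features",
    "percentile_normalize",
    "PercentileNormalizer",
    "BufferFeatureExtractor",
    "extract_cohort_features",
]

#: land-use class labels treated as residential
RESIDENTIAL_CLASSES = frozenset(
    {"private residential", "public residential", "rural settlement"}
)

FEATURE_COLUMNS = [
    "pct_residential",
    "pct_vegetation",
    "avg_build_height_m",
    "std_build_height_m",
]
PCTILE_COLUMNS = ["avg_build_height_pctile", "std_build_height_pctile"]


@dataclass
class BufferFeatureSet:
    """Raw buffer measures for one location (percentiles filled in later)."""

    pct_residential: float
    pct_vegetation: float
    avg_build_height_m: float
    std_build_height_m: float
    no_buildings: bool = False          # no built cell in the buffer
    edge_clipped: bool = False          # >50% of the buffer fell outside the extent
    avg_build_height_pctile: float | None = None
    std_build_height_pctile: float | None = None


def binarize_landuse(
    land_use: RasterLayer, residential_classes: frozenset[str] | set[str] = RESIDENTIAL_CLASSES
) -> RasterLayer:
    """0/1 residential mask from a categorical land-use layer.

    Unknown labels in ``residential_classes`` raise a warning, not an error;
    nodata cells stay nodata.
    """
    if not residential_classes:
        raise ValueError("residential_classes must be non-empty")
    if land_use.categories is None:
        raise ValueError("land-use layer has no category labels")
    labels = set(land_use.categories.values())
    unknown = set(residential_classes) - labels
    if unknown:
        warnings.warn(f"unknown land-use class labels ignored: {sorted(unknown)}")
    res_codes = [c for c, lab in land_use.categories.items() if lab in residential_classes]
    out = np.where(np.isin(land_use.values, res_codes), 1.0, 0.0)
    out[~land_use.valid_mask()] = np.nan
    return RasterLayer(values=out, origin=land_use.origin,
                       resolution_m=land_use.resolution_m, nodata=land_use.nodata)


def _std(values: np.ndarray) -> float:
    # population SD; 0 whenever <=1 distinct value
    return float(np.std(values)) if values.size else 0.0


def buffer_features(
    x: float,
    y: float,
    residential: RasterLayer,
    vegetation: RasterLayer,
    building_height: RasterLayer,
    radius_m: float = 400.0,
    built_cells_only: bool = True,
) -> BufferFeatureSet:
    """Compute the four raw buffer measures at a point.

    ``built_cells_only`` switches whether height statistics run over built
    cells (height > 0, the default) or over every valid cell with unbuilt
    ground entering as height 0.
    """
    for name, layer in (("vegetation", vegetation), ("building_height", building_height)):
        if not residential.is_coregistered(layer):
            raise ValueError(f"{name} layer is not co-registered with the residential layer")
    res = residential.resolution_m
    xmin, ymin, xmax, ymax = residential.extent
    if not (xmin <= x < xmax and ymin <= y < ymax):
        raise ValueError(f"point ({x}, {y}) outside raster extent")

    # window of rows/cols that can intersect the buffer, then a centre-distance mask
    nrows, ncols = residential.shape
    c0 = max(int((x - radius_m - xmin) // res), 0)
    c1 = min(int((x + radius_m - xmin) // res) + 1, ncols)
    r0 = max(int((y - radius_m - ymin) // res), 0)
    r1 = min(int((y + radius_m - ymin) // res) + 1, nrows)
    xs = xmin + (np.arange(c0, c1) + 0.5) * res
    ys = ymin + (np.arange(r0, r1) + 0.5) * res
    in_buf = ((xs[None, :] - x) ** 2 + (ys[:, None] - y) ** 2) <= radius_m**2
    if not in_buf.any():
        raise ValueError("buffer contains no cells")

    res_w = residential.values[r0:r1, c0:c1][in_buf]
    veg_w = vegetation.values[r0:r1, c0:c1][in_buf]
    bh_w = building_height.values[r0:r1, c0:c1][in_buf]

    valid = np.isfinite(res_w)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("buffer contains no valid cells")
    # flag buffers more than half outside the extent (or nodata)
    full_cells = np.pi * radius_m**2 / res**2
    edge_clipped = n_valid < 0.5 * full_cells

    pct_res = 100.0 * float(np.nansum(res_w)) / n_valid
    pct_veg = 100.0 * float(np.nansum(veg_w)) / int(np.isfinite(veg_w).sum())

    heights = bh_w[np.isfinite(bh_w)]
    if built_cells_only:
        heights = heights[heights > 0]
    if heights.size == 0:
        return BufferFeatureSet(pct_res, pct_veg, 0.0, 0.0,
                                no_buildings=True, edge_clipped=edge_clipped)
    return BufferFeatureSet(pct_res, pct_veg, float(np.mean(heights)), _std(heights),
                            no_buildings=False, edge_clipped=edge_clipped)


def _disk_kernel(radius_m: float, resolution_m: float) -> np.ndarray:
    n = int(radius_m // resolution_m) + 1
    offs = (np.arange(-n, n + 1)) * resolution_m
    return ((offs[None, :] ** 2 + offs[:, None] ** 2) <= radius_m**2).astype(float)


def moving_window_features(
    residential: RasterLayer,
    vegetation: RasterLayer,
    building_height: RasterLayer,
    radius_m: float = 400.0,
    built_cells_only: bool = True,
) -> dict[str, RasterLayer]:
    """Citywide buffer summaries: the same four measures evaluated at every
    cell centre, via FFT convolution with a disk kernel.

    Cells whose buffer holds no valid (or, under ``built_cells_only``, no
    built) cell get NaN for the height measures.  Used for mapping, and as a
    fast cohort-extraction path when subjects are snapped to cell centres.
    """
    for name, layer in (("vegetation", vegetation), ("building_height", building_height)):
        if not residential.is_coregistered(layer):
            raise ValueError(f"{name} layer is not co-registered with the residential layer")
    res = residential.resolution_m
    kern = _disk_kernel(radius_m, res)

    def conv(a: np.ndarray) -> np.ndarray:
        return signal.fftconvolve(a, kern, mode="same")

    valid = residential.valid_mask().astype(float)
    n_valid = conv(valid)
    n_valid = np.where(n_valid > 0.5, np.round(n_valid), np.nan)

    res_vals = np.nan_to_num(residential.values)
    veg_vals = np.nan_to_num(vegetation.values)
    bh_vals = np.nan_to_num(building_height.values)

    pct_res = 100.0 * conv(res_vals * valid) / n_valid
    pct_veg = 100.0 * conv(veg_vals * valid) / n_valid

    built = ((bh_vals > 0) & (valid > 0)).astype(float) if built_cells_only else valid
    n_built = np.round(conv(built))
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = conv(bh_vals * built)
        s2 = conv(bh_vals**2 * built)
        avg = np.where(n_built > 0.5, s1 / np.maximum(n_built, 1), np.nan)
        var = np.where(n_built > 0.5, s2 / np.maximum(n_built, 1) - avg**2, np.nan)
        std = np.sqrt(np.clip(var, 0.0, None))

    meta = dict(origin=residential.origin, resolution_m=res, nodata=residential.nodata)
    return {
        "pct_residential": RasterLayer(values=np.clip(pct_res, 0, 100), **meta),
        "pct_vegetation": RasterLayer(values=np.clip(pct_veg, 0, 100), **meta),
        "avg_build_height_m": RasterLayer(values=avg, **meta),
        "std_build_height_m": RasterLayer(values=std, **meta),
    }


def percentile_normalize(values) -> np.ndarray:
    """Hazen percentile ranks on a 0–100 scale.

    ``percentile_i = 100 * (rank_i - 0.5) / n`` with average ranks for ties:
    order-preserving, invariant under strictly monotone transforms, and a
    constant vector maps to all-50.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot percentile-normalize an empty vector")
    if not np.isfinite(values).all():
        raise ValueError("percentile_normalize requires finite values")
    ranks = rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / values.size


class PercentileNormalizer(BaseEstimator, TransformerMixin):
    """Map columns to empirical percentiles (0–100) of the fitted sample.

    ``fit_transform`` on the reference sample reproduces the Hazen ranks of
    :func:`percentile_normalize`; ``transform`` places new values on the same
    scale via the reference empirical distribution.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] == 0 or not np.isfinite(X).all():
            raise ValueError("fit requires a non-empty finite sample")
        self.reference_ = [np.sort(X[:, j]) for j in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = np.empty_like(X)
        for j, ref in enumerate(self.reference_):
            lo = np.searchsorted(ref, X[:, j], side="left")
            hi = np.searchsorted(ref, X[:, j], side="right")
            rank = lo + (hi - lo + 1) / 2.0
            out[:, j] = 100.0 * (rank - 0.5) / ref.size
        return out[:, 0] if squeeze else out


class BufferFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing buffer features for an array of (x, y) points.

    Parameters
    ----------
    radius_m : buffer radius in metres (study protocol: 400 m).
    working_resolution_m : resolution the layers are resampled to before
        extraction (study protocol: 1 m; ``None`` keeps the native grid —
        exact for piecewise-constant layers and much faster).
    built_cells_only : whether height statistics exclude unbuilt ground.
    cell_approx : snap points to cell centres and use the FFT moving-window
        path; fast for large cohorts, within sampling error of exact buffers.
    """

    def __init__(self, radius_m: float = 400.0, working_resolution_m: float | None = None,
                 built_cells_only: bool = True, cell_approx: bool = False):
        self.radius_m = radius_m
        self.working_resolution_m = working_resolution_m
        self.built_cells_only = built_cells_only
        self.cell_approx = cell_approx

    def fit(self, X=None, y=None, *, residential: RasterLayer,
            vegetation: RasterLayer, building_height: RasterLayer):
        layers = (residential, vegetation, building_height)
        if self.working_resolution_m is not None:
            layers = tuple(resample_raster(l, self.working_resolution_m) for l in layers)
        self.residential_, self.vegetation_, self.building_height_ = layers
        if self.cell_approx:
            self.window_layers_ = moving_window_features(
                *layers, radius_m=self.radius_m, built_cells_only=self.built_cells_only
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of x/y coordinates")
        rows = []
        if self.cell_approx:
            wl = self.window_layers_
            for x, y in X:
                r, c = self.residential_.cell_index(x, y)
                avg = wl["avg_build_height_m"].values[r, c]
                std = wl["std_build_height_m"].values[r, c]
                nb = not np.isfinite(avg)
                rows.append(dict(
                    pct_residential=wl["pct_residential"].values[r, c],
                    pct_vegetation=wl["pct_vegetation"].values[r, c],
                    avg_build_height_m=0.0 if nb else avg,
                    std_build_height_m=0.0 if nb else std,
                    no_buildings=nb, edge_clipped=False,
                ))
        else:
            for x, y in X:
                f = buffer_features(x, y, self.residential_, self.vegetation_,
                                    self.building_height_, radius_m=self.radius_m,
                                    built_cells_only=self.built_cells_only)
                rows.append(dict(
                    pct_residential=f.pct_residential, pct_vegetation=f.pct_vegetation,
                    avg_build_height_m=f.avg_build_height_m,
                    std_build_height_m=f.std_build_height_m,
                    no_buildings=f.no_buildings, edge_clipped=f.edge_clipped,
                ))
        return pd.DataFrame(rows, index=pd.RangeIndex(len(rows)))


def extract_cohort_features(
    cohort: pd.DataFrame,
    residential: RasterLayer,
    vegetation: RasterLayer,
    building_height: RasterLayer,
    radius_m: float = 400.0,
    working_resolution_m: float | None = None,
    built_cells_only: bool = True,
    cell_approx: bool = False,
) -> pd.DataFrame:
    """Buffer features for every cohort subject, plus study-wide height
    percentiles (columns ``avg_build_height_pctile``/``std_build_height_pctile``).
    """
    ext = BufferFeatureExtractor(
        radius_m=radius_m, working_resolution_m=working_resolution_m,
        built_cells_only=built_cells_only, cell_approx=cell_approx,
    ).fit(residential=residential, vegetation=vegetation, building_height=building_height)
    feats = ext.transform(cohort[["x", "y"]].to_numpy())
    feats.index = cohort.index
    for raw, pct in zip(["avg_build_height_m", "std_build_height_m"], PCTILE_COLUMNS):
        feats[pct] = percentile_normalize(feats[raw].to_numpy())
    return feats
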