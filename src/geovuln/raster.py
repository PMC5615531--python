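"""Planar raster grids.

A :class:`RasterLayer` is a rectangular grid of cell values registered to a
planar coordinate system in metres: ``origin`` is the (x, y) of the grid's
lower-left corner, ``resolution_m`` the cell edge length.  Row 0 of ``values``
is the *southernmost* row, so ``values[r, c]`` covers the half-open cell

    x in [x0 + c*res, x0 + (c+1)*res),  y in [y0 + r*res, y0 + (r+1)*res).

Invalid cells are stored as NaN in memory regardless of the on-disk nodata
sentinel.  Land-use layers carry an integer-code -> class-label mapping in
``categories``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterLayer", "resample_raster"]


@dataclass
class RasterLayer:
    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    resolution_m: float = 10.0
    nodata: float = -9999.0
    categories: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.resolution_m > 0:
            raise ValueError("resolution_m must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        # normalise the on-disk sentinel to NaN in memory
        if np.isfinite(self.nodata):
            self.values[self.values == self.nodata] = np.nan

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.resolution_m, y0 + nrows * self.resolution_m)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y) under the half-open rule."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x < xmax and ymin <= y < ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = int((x - xmin) // self.resolution_m)
        row = int((y - ymin) // self.resolution_m)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x coordinates of column centres and y of row centres."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        res = self.resolution_m
        xs = x0 + (np.arange(ncols) + 0.5) * res
        ys = y0 + (np.arange(nrows) + 0.5) * res
        return xs, ys

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def is_coregistered(self, other: "RasterLayer", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-6)
            and np.isclose(self.resolution_m, other.resolution_m, rtol=rtol)
        )

    def copy(self) -> "RasterLayer":
        return replace(self, values=self.values.copy(),
                       categories=dict(self.categories) if self.categories else None)


def resample_raster(layer: RasterLayer, target_resolution_m: float) -> RasterLayer:
    """Nearest-neighbour resampling to a new cell size.

    Each target cell takes the value of the source cell containing its centre,
    so refining a grid (e.g. 10 m -> 1 m) preserves every value exactly.
    """
    if not target_resolution_m > 0:
        raise ValueError("target_resolution_m must be positive")
    if np.isclose(target_resolution_m, layer.resolution_m):
        return layer.copy()
    xmin, ymin, xmax, ymax = layer.extent
    ncols_t = int(round((xmax - xmin) / target_resolution_m))
    nrows_t = int(round((ymax - ymin) / target_resolution_m))
    xs = xmin + (np.arange(ncols_t) + 0.5) * target_resolution_m
    ys = ymin + (np.arange(nrows_t) + 0.5) * target_resolution_m
    cols = np.clip(((xs - xmin) // layer.resolution_m).astype(int), 0, layer.shape[1] - 1)
    rows = np.clip(((ys - ymin) // layer.resolution_m).astype(int), 0, layer.shape[0] - 1)
    values = layer.values[np.ix_(rows, cols)]
    return RasterLayer(values=values, origin=layer.origin,
                       resolution_m=target_resolution_m, nodata=layer.nodata,
                       categories=dict(layer.categories) if layer.categories else None)
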