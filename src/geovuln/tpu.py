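"""Planning-unit (TPU) zones.

The mapping/aggregation unit is a grid of rectangular planning zones tiling
the city extent, each carrying a census attribute ``pct_low_education``
(percentage of the zone's population with elementary education or below,
0-100).  Zone membership of a point or cell centre uses the half-open
rectangle convention [xmin, xmax) x [ymin, ymax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .raster import RasterLayer

__all__ = ["TPUZone", "TPUGrid"]


@dataclass(frozen=True)
class TPUZone:
    tpu_id: int
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    pct_low_education: float

    def __post_init__(self):
        if not 0.0 <= self.pct_low_education <= 100.0:
            raise ValueError("pct_low_education must be within [0, 100]")

    @property
    def polygon(self):
        return box(*self.bounds)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin <= y < ymax


@dataclass
class TPUGrid:
    zones: list[TPUZone]

    def __post_init__(self):
        if not self.zones:
            raise ValueError("TPU grid must contain at least one zone")
        ids = [z.tpu_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        b = np.array([z.bounds for z in self.zones])
        return (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())

    def total_zone_area(self) -> float:
        return float(sum(z.polygon.area for z in self.zones))

    def zone_of_point(self, x: float, y: float) -> TPUZone | None:
        for z in self.zones:
            if z.contains(x, y):
                return z
        return None

    def zone_id_grid(self, template: RasterLayer) -> np.ndarray:
        """Integer array of zone ids per template cell centre (-1 outside all zones)."""
        xs, ys = template.cell_centers()
        out = np.full(template.shape, -1, dtype=int)
        for z in self.zones:
            xmin, ymin, xmax, ymax = z.bounds
            cin = (xs >= xmin) & (xs < xmax)
            rin = (ys >= ymin) & (ys < ymax)
            out[np.ix_(rin, cin)] = z.tpu_id
        return out

    def rasterize_attribute(self, template: RasterLayer,
                            attribute: str = "pct_low_education") -> RasterLayer:
        """Zone-constant raster of a census attribute on the template grid."""
        ids = self.zone_id_grid(template)
        values = np.full(template.shape, np.nan)
        for z in self.zones:
            values[ids == z.tpu_id] = getattr(z, attribute)
        return RasterLayer(values=values, origin=template.origin,
                           resolution_m=template.resolution_m, nodata=template.nodata)
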