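"""Socio-environmental vulnerability index.

The index is a linear combination of the mapping layers, weighted by the
percentage risk increase each retained variable carries in the adjusted
(Model 3) regression:

    index = sum_k w_k * layer_k,   w_k = OR_k - 1,

with the weight further divided by 100 for a binary variable that enters the
map as an area-level population percentage (low education).  Only variables
whose Model-3 95% CI excludes 1 are retained.  With the published adjusted
ORs (1.60 low education, 1.01 pct residential, 0.98 avg height percentile,
1.03 std height percentile) this gives

    index = 0.006*pct_low_education + 0.01*pct_residential
            - 0.02*avg_height_pctile + 0.03*std_height_pctile.

The index surface is computed cellwise at the mapping resolution (10 m) and
aggregated to planning units (zone mean, binned to the 0.1 scale unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterLayer
from .risk_models import ORResult
from .tpu import TPUGrid

__all__ = [
    "VariableKind",
    "IndexWeights",
    "VulnRaster",
    "derive_weights",
    "compute_index_raster",
    "aggregate_to_tpu",
    "DEFAULT_VARIABLE_KINDS",
    "plot_index_map",
]

#: how each candidate variable enters the map
DEFAULT_VARIABLE_KINDS = {
    "older_ages": "binary-population-percentage",
    "male": "binary-population-percentage",
    "not_married": "binary-population-percentage",
    "low_education": "binary-population-percentage",
    "living_alone": "binary-population-percentage",
    "pct_residential": "continuous-percentage",
    "pct_vegetation": "continuous-percentage",
    "avg_build_height_pctile": "continuous-percentage",
    "std_build_height_pctile": "continuous-percentage",
}

#: mapping-layer name used for each retained regression variable
LAYER_FOR_VARIABLE = {
    "low_education": "pct_low_education",
    "pct_residential": "pct_residential",
    "pct_vegetation": "pct_vegetation",
    "avg_build_height_pctile": "avg_build_height_pctile",
    "std_build_height_pctile": "std_build_height_pctile",
}


@dataclass(frozen=True)
class IndexWeights:
    """Signed weights per retained variable, keyed by variable name."""

    weights: dict[str, float]
    kinds: dict[str, str]

    def __post_init__(self):
        if not self.weights:
            raise ValueError("index has no weights")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def formula(self) -> str:
        parts = []
        for name, w in self.weights.items():
            sign = "-" if w < 0 else "+"
            parts.append(f"{sign} {abs(w):g}*{name}")
        s = " ".join(parts)
        return s[2:] if s.startswith("+ ") else s


@dataclass
class VulnRaster:
    """Index surface plus the provenance that produced it."""

    layer: RasterLayer
    weights: IndexWeights
    input_layers: tuple[str, ...]


def derive_weights(model3_ors: dict[str, ORResult],
                   kinds: dict[str, str] | None = None,
                   round_dp: int | None = 2) -> IndexWeights:
    """Index weights from adjusted ORs: significant variables only,
    weight = OR - 1, divided by 100 for binary-population-percentage
    variables.

    ORs are taken at 2-dp presentation precision by default
    (``round_dp=None`` uses them unrounded, for synthetic experiments).
    """
    kinds = kinds or DEFAULT_VARIABLE_KINDS
    weights: dict[str, float] = {}
    used_kinds: dict[str, str] = {}
    for name, res in model3_ors.items():
        if name not in kinds:
            continue  # confounders never enter the index
        if not res.significant:
            continue
        or_point = round(res.or_point, round_dp) if round_dp is not None else res.or_point
        w = or_point - 1.0
        if kinds[name] == "binary-population-percentage":
            w /= 100.0
        w = round(w, round_dp + 2) if round_dp is not None else w
        weights[name] = w
        used_kinds[name] = kinds[name]
    if not weights:
        raise ValueError("no significant variables; cannot build an index")
    return IndexWeights(weights=weights, kinds=used_kinds)


def compute_index_raster(weights: IndexWeights,
                         layers: dict[str, RasterLayer]) -> VulnRaster:
    """Cellwise weighted sum of co-registered mapping layers.

    ``layers`` is keyed by mapping-layer name (e.g. ``pct_low_education``);
    nodata in any input propagates to the output cell.
    """
    needed = [LAYER_FOR_VARIABLE.get(v, v) for v in weights.weights]
    missing = [n for n in needed if n not in layers]
    if missing:
        raise ValueError(f"missing required mapping layers: {missing}")
    first = layers[needed[0]]
    acc = np.zeros(first.shape)
    for var, w in weights.weights.items():
        layer = layers[LAYER_FOR_VARIABLE.get(var, var)]
        if not first.is_coregistered(layer):
            raise ValueError(f"layer '{var}' is not co-registered")
        acc = acc + w * layer.values  # NaN propagates
    out = RasterLayer(values=acc, origin=first.origin,
                      resolution_m=first.resolution_m, nodata=first.nodata)
    return VulnRaster(layer=out, weights=weights, input_layers=tuple(needed))


def aggregate_to_tpu(vuln: VulnRaster, tpus: TPUGrid) -> pd.DataFrame:
    """Zone means of the index, binned to the nearest 0.1 scale unit.

    Zones without any valid cell are flagged (``no_data=True``) and carry no
    number, emulating unsettled areas left blank on the map.
    """
    ids = tpus.zone_id_grid(vuln.layer)
    vals = vuln.layer.values
    records = []
    for z in tpus.zones:
        cell_vals = vals[ids == z.tpu_id]
        cell_vals = cell_vals[np.isfinite(cell_vals)]
        if cell_vals.size == 0:
            records.append(dict(tpu_id=z.tpu_id, index_mean=np.nan,
                                index_binned=np.nan, n_cells=0, no_data=True))
        else:
            m = float(cell_vals.mean())
            records.append(dict(tpu_id=z.tpu_id, index_mean=m,
                                index_binned=float(np.round(m, 1)),
                                n_cells=int(cell_vals.size), no_data=False))
    return pd.DataFrame.from_records(records)


def plot_index_map(vuln: VulnRaster, ax=None, cmap: str = "RdYlBu_r"):
    """Minimal choropleth-style rendering of the index surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xmin, ymin, xmax, ymax = vuln.layer.extent
    im = ax.imshow(vuln.layer.values, origin="lower", cmap=cmap,
                   extent=(xmin, xmax, ymin, ymax))
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.figure.colorbar(im, ax=ax, label="socio-environmental vulnerability index")
    return ax
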