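import numpy as np
import pandas as pd
import pytest

from geovuln.env_features import binarize_landuse, extract_cohort_features
from geovuln.raster import RasterLayer
from geovuln.synthetic_city import (LAND_USE_CATEGORIES, CityConfig,
                                    generate_cohort, generate_rasters,
                                    generate_tpu_grid, simulate_outcomes)


@pytest.fixture(scope="session")
def default_city():
    """The default synthetic city at seed 1: rasters, TPUs, cohort with
    outcomes and exact per-point buffer features.  Session-scoped: every
    consumer treats it as read-only."""
    cfg = CityConfig(seed=1)
    land_use, veg, bh = generate_rasters(cfg)
    tpus = generate_tpu_grid(cfg)
    residential = binarize_landuse(land_use)
    cohort = generate_cohort(cfg, land_use, tpus=tpus)
    feats = extract_cohort_features(cohort, residential, veg, bh)
    cohort = simulate_outcomes(cohort, feats, cfg)
    return dict(config=cfg, land_use=land_use, vegetation=veg,
                building_height=bh, residential=residential, tpus=tpus,
                cohort=cohort, features=feats,
                data=pd.concat([cohort, feats], axis=1))


@pytest.fixture()
def small_config():
    """A small, fast city for smoke/determinism tests."""
    return CityConfig(extent_m=1000.0, base_resolution_m=10.0, n_tpu=4,
                      n_subjects=300, seed=7)


@pytest.fixture()
def toy_layers():
    """Tiny co-registered 9x9 layers with known content (res 10 m)."""
    n = 9
    meta = dict(origin=(0.0, 0.0), resolution_m=10.0, nodata=-9999.0)
    land = np.zeros((n, n))
    land[:, :4] = 1.0  # west half residential
    lu = RasterLayer(values=land, categories=dict(LAND_USE_CATEGORIES), **meta)
    veg = RasterLayer(values=np.tile([1.0, 0.0, 0.0], (n, 3)), **meta)
    heights = np.zeros((n, n))
    heights[2:5, 2:5] = 20.0
    heights[6:8, 6:8] = 50.0
    bh = RasterLayer(values=heights, **meta)
    return lu, veg, bh
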