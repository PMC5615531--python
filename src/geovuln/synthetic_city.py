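"""Synthetic city and cohort generator.

Because the original survey and GIS layers are not deposited, every
downstream stage is exercised on a simulated high-density city: a blocky
patch model of residential estates, vegetation patches and building clusters
with heterogeneous heights, a rectangular planning-unit (TPU) grid with a
low-education census attribute, and a geocoded cohort of older adults whose
depression-case indicator is drawn from the same logistic model the analysis
later fits, with configurable true coefficients.

Design choices the generator encodes (documented in the methods note):

* building heights are log-normal around a per-cluster regime mean with a
  per-cluster spread, which yields 400-m-buffer mean and SD of building
  height that are strongly positively correlated (target r ~ 0.8) the way
  mixed historical/redeveloped districts are;
* social covariates are drawn through a Gaussian copula so not-married and
  living-alone carry substantial positive dependence (target Pearson phi
  0.55) while marginal rates default to the control-group rates;
* individual low education is spatially structured: a subject's probability
  is shifted by their TPU's census low-education attribute while preserving
  the study-wide marginal rate;
* a case's GDS-15 score is drawn uniformly from 8-15 and a control's from
  0-7, so the score and the case indicator are consistent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

from .raster import RasterLayer
from .tpu import TPUGrid, TPUZone

__all__ = [
    "LAND_USE_CATEGORIES",
    "RESIDENTIAL_CODES",
    "BETA_TERMS",
    "CityConfig",
    "generate_rasters",
    "generate_tpu_grid",
    "generate_cohort",
    "simulate_outcomes",
    "inject_missing",
]

LAND_USE_CATEGORIES = {
    0: "open land",
    1: "private residential",
    2: "public residential",
    3: "rural settlement",
    4: "commercial",
    5: "industrial",
}
RESIDENTIAL_CODES = (1, 2, 3)

#: predictor order matched by ``CityConfig.true_betas[1:]`` (intercept first)
BETA_TERMS = [
    "older_ages", "male", "not_married", "low_education", "living_alone",
    "pct_residential", "pct_vegetation",
    "avg_build_height_pctile", "std_build_height_pctile",
    "dementia", "physical_activity", "cardiovascular", "respiratory",
    "alcohol", "smoking",
]


def _default_betas() -> np.ndarray:
    """Exposure effects sized like the adjusted Model-3 odds ratios; the
    confounder effects are generator assumptions (their coding is ours)."""
    ors = {
        "older_ages": 1.26, "male": 1.13, "not_married": 1.24,
        "low_education": 1.60, "living_alone": 1.31,
        "pct_residential": 1.01, "pct_vegetation": 1.00,
        "avg_build_height_pctile": 0.98, "std_build_height_pctile": 1.03,
        "dementia": 1.8, "cardiovascular": 1.3, "respiratory": 1.2,
        "alcohol": 1.1, "smoking": 1.2,
    }
    betas = [0.0]  # intercept, re-calibrated to the prevalence target
    for term in BETA_TERMS:
        betas.append(-0.10 if term == "physical_activity" else float(np.log(ors[term])))
    return np.array(betas)


@dataclass
class CityConfig:
    """Parameters of the synthetic city, cohort and outcome model."""

    extent_m: float = 4000.0
    base_resolution_m: float = 10.0
    n_tpu: int = 25
    n_subjects: int = 4000
    seed: int = 0
    residential_fraction: float = 0.30
    vegetation_fraction: float = 0.25
    covariate_rates: dict[str, float] = field(default_factory=lambda: {
        # control-group marginal rates
        "older_ages": 0.095, "male": 0.505, "not_married": 0.281,
        "low_education": 0.655, "living_alone": 0.129,
    })
    confounder_rates: dict[str, float] = field(default_factory=lambda: {
        "dementia": 0.05, "cardiovascular": 0.20, "respiratory": 0.10,
        "alcohol": 0.15, "smoking": 0.10,
    })
    nm_la_corr: float = 0.55        # target Pearson r(not_married, living_alone)
    true_betas: np.ndarray = field(default_factory=_default_betas)
    prevalence_target: float | None = 364 / 3930
    missing_rate: float = 0.0035    # fraction of rows given one missing field

    def __post_init__(self):
        if not self.extent_m > 0:
            raise ValueError("extent_m must be positive")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if not self.base_resolution_m > 0:
            raise ValueError("base_resolution_m must be positive")
        n_cells = self.extent_m / self.base_resolution_m
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("base_resolution_m must divide extent_m")
        self.true_betas = np.asarray(self.true_betas, dtype=float)
        if self.true_betas.shape != (16,):
            raise ValueError("true_betas must have exactly 16 entries "
                             "(intercept + 15 predictors)")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def _place_patches(rng, grid, target_fraction, codes, code_probs, size_range):
    """Fill random rectangles with class codes until a cover fraction is met."""
    n = grid.shape[0]
    lo, hi = size_range
    target_cells = target_fraction * grid.size
    guard = 0
    while (np.isin(grid, codes).sum() < target_cells) and guard < 10_000:
        guard += 1
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        r = int(rng.integers(0, max(n - h, 1)))
        c = int(rng.integers(0, max(n - w, 1)))
        code = int(rng.choice(codes, p=code_probs))
        grid[r:r + h, c:c + w] = code


def _rect_list(mask: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Connected rectangular-ish chunks of a mask, as coarse bounding tiles."""
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    rects = []
    for sl in ndimage.find_objects(labels):
        if sl is not None:
            rects.append((sl[0].start, sl[0].stop, sl[1].start, sl[1].stop))
    return rects


def generate_rasters(config: CityConfig) -> tuple[RasterLayer, RasterLayer, RasterLayer]:
    """Land-use, vegetation-mask and building-height layers (co-registered).

    Deterministic in ``config.seed``.  Building clusters are seeded inside
    residential and commercial patches; each cluster draws a height regime
    (log-normal mean) and a spread, and individual buildings scatter
    log-normally around the regime.
    """
    rng = config.rng(1)
    n = int(round(config.extent_m / config.base_resolution_m))
    land = np.zeros((n, n), dtype=float)

    if config.residential_fraction >= 0.999:
        land[:] = rng.choice(RESIDENTIAL_CODES, size=land.shape)
    else:
        # residential estates (larger) and rural settlements (smaller patches)
        _place_patches(rng, land, config.residential_fraction * 0.85,
                       codes=(1, 2), code_probs=(0.45, 0.55),
                       size_range=(max(2, n // 40), max(3, n // 10)))
        _place_patches(rng, land, config.residential_fraction,
                       codes=RESIDENTIAL_CODES, code_probs=(0.0, 0.0, 1.0),
                       size_range=(max(1, n // 80), max(2, n // 25)))
        # some commercial / industrial fabric on what is left
        nonres = land == 0
        com = np.zeros_like(land)
        _place_patches(rng, com, 0.10, codes=(4, 5), code_probs=(0.6, 0.4),
                       size_range=(max(2, n // 50), max(3, n // 16)))
        land[nonres & (com > 0)] = com[nonres & (com > 0)]

    vegetation = np.zeros((n, n), dtype=float)
    _place_patches(rng, vegetation, config.vegetation_fraction, codes=(1,),
                   code_probs=(1.0,), size_range=(max(2, n // 40), max(3, n // 8)))

    # building clusters inside developed patches
    height = np.zeros((n, n), dtype=float)
    developed = np.isin(land, (1, 2, 4, 5))
    rural = land == 3
    for r0, r1, c0, c1 in _rect_list(developed | rural):
        patch_is_rural = rural[r0:r1, c0:c1].mean() > 0.5
        if rng.random() < (0.15 if patch_is_rural else 0.05):
            continue  # undeveloped patch
        if patch_is_rural:
            regime = float(np.exp(rng.normal(np.log(7.0), 0.3)))
            sigma = rng.uniform(0.1, 0.3)
        else:
            regime = float(np.exp(rng.normal(np.log(26.0), 0.75)))
            sigma = rng.uniform(0.40, 0.90)
        coverage = rng.uniform(0.25, 0.55)
        area = (r1 - r0) * (c1 - c0)
        fp = max(1, int(rng.integers(2, 5)))  # building footprint edge, in cells
        n_buildings = max(1, int(coverage * area / fp**2))
        for _ in range(n_buildings):
            rr = int(rng.integers(r0, max(r1 - fp, r0 + 1)))
            cc = int(rng.integers(c0, max(c1 - fp, c0 + 1)))
            h = float(np.clip(regime * np.exp(rng.normal(0.0, sigma)), 3.0, 400.0))
            height[rr:rr + fp, cc:cc + fp] = h

    meta = dict(origin=(0.0, 0.0), resolution_m=config.base_resolution_m, nodata=-9999.0)
    land_use = RasterLayer(values=land, categories=dict(LAND_USE_CATEGORIES), **meta)
    veg = RasterLayer(values=vegetation, **meta)
    bh = RasterLayer(values=height, **meta)
    return land_use, veg, bh


def generate_tpu_grid(config: CityConfig) -> TPUGrid:
    """Rectangular planning-unit tiles with a low-education census attribute.

    ``n_tpu`` is factorised into the most square rows x cols tiling; the
    attribute is Beta-distributed with mean matching the study-wide
    low-education rate and realistic between-zone spread (~12 points).
    """
    rng = config.rng(2)
    n_tpu = config.n_tpu
    rows = int(np.floor(np.sqrt(n_tpu)))
    while n_tpu % rows:
        rows -= 1
    cols = n_tpu // rows
    dx, dy = config.extent_m / cols, config.extent_m / rows
    mean = config.covariate_rates["low_education"]
    var = 0.12**2
    ab = mean * (1 - mean) / var - 1
    alpha, beta = mean * ab, (1 - mean) * ab
    zones = []
    for i in range(rows):
        for j in range(cols):
            pct = float(100 * rng.beta(alpha, beta))
            zones.append(TPUZone(tpu_id=i * cols + j,
                                 bounds=(j * dx, i * dy, (j + 1) * dx, (i + 1) * dy),
                                 pct_low_education=pct))
    return TPUGrid(zones=zones)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _latent_rho(p1: float, p2: float, target_phi: float) -> float:
    """Latent bivariate-normal correlation giving a target Pearson phi for
    two Bernoulli margins under a Gaussian copula."""
    t1, t2 = norm.ppf(1 - p1), norm.ppf(1 - p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi_of(rho: float) -> float:
        bv = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        p11 = bv.cdf([-t1, -t2])  # P(z1 > t1, z2 > t2) by symmetry
        return (p11 - p1 * p2) / denom

    lo, hi = -0.995, 0.9995
    if target_phi >= phi_of(hi):
        warnings.warn("target phi exceeds the copula's attainable range; clamped")
        return hi
    if target_phi <= phi_of(lo):
        warnings.warn("target phi below the copula's attainable range; clamped")
        return lo
    return float(brentq(lambda r: phi_of(r) - target_phi, lo, hi, xtol=1e-6))


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    if w.min() > 1e-10:
        return corr
    w = np.clip(w, 1e-8, None)
    m = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


# latent correlations among [older_ages, living_alone, low_education,
# not_married, male]; the LA-NM entry is solved exactly for the target phi
_SOCIAL_ORDER = ["older_ages", "living_alone", "low_education", "not_married", "male"]
_LATENT_BASE = {
    ("older_ages", "living_alone"): 0.25,
    ("older_ages", "low_education"): 0.12,
    ("older_ages", "not_married"): 0.40,
    ("older_ages", "male"): -0.05,
    ("living_alone", "low_education"): 0.12,
    ("living_alone", "male"): -0.35,
    ("low_education", "not_married"): 0.35,
    ("low_education", "male"): -0.45,
    ("not_married", "male"): -0.60,
}


def generate_cohort(config: CityConfig, land_use: RasterLayer,
                    tpus: TPUGrid | None = None) -> pd.DataFrame:
    """Geocoded cohort of older adults on residential cells (no outcome yet).

    Social covariates come from a Gaussian copula with the configured
    marginal rates; when ``tpus`` is given, each subject's low-education
    probability is shifted with their zone's census attribute (preserving
    the study-wide marginal).  Lifestyle/medical confounders are independent
    Bernoulli draws plus a non-negative activity score.
    """
    rng = config.rng(3)
    res_mask = np.isin(land_use.values, RESIDENTIAL_CODES)
    if not res_mask.any():
        raise ValueError("land-use layer has no residential cells")
    if config.n_subjects == 0:
        return pd.DataFrame(columns=["subject_id", "x", "y", *BETA_TERMS[:5],
                                     "dementia", "physical_activity", "cardiovascular",
                                     "respiratory", "alcohol", "smoking"])

    rows, cols = np.nonzero(res_mask)
    pick = rng.integers(0, len(rows), size=config.n_subjects)
    res = land_use.resolution_m
    x0, y0 = land_use.origin
    x = x0 + (cols[pick] + rng.random(config.n_subjects)) * res
    y = y0 + (rows[pick] + rng.random(config.n_subjects)) * res

    rates = config.covariate_rates
    corr = np.eye(5)
    pairs = dict(_LATENT_BASE)
    pairs[("living_alone", "not_married")] = _latent_rho(
        rates["not_married"], rates["living_alone"], config.nm_la_corr)
    for (u, v), rho in pairs.items():
        i, j = _SOCIAL_ORDER.index(u), _SOCIAL_ORDER.index(v)
        corr[i, j] = corr[j, i] = rho
    corr = _nearest_psd(corr)
    z = rng.multivariate_normal(np.zeros(5), corr, size=config.n_subjects,
                                method="cholesky")

    data: dict[str, np.ndarray] = {}
    for k, name in enumerate(_SOCIAL_ORDER):
        p = np.full(config.n_subjects, rates[name])
        if name == "low_education" and tpus is not None:
            zone_pct = np.array([
                (tpus.zone_of_point(xi, yi).pct_low_education
                 if tpus.zone_of_point(xi, yi) else 100 * rates[name])
                for xi, yi in zip(x, y)
            ]) / 100.0
            # centre the zone signal on the cohort so the marginal stays on target
            p = np.clip(rates[name] + 0.5 * (zone_pct - zone_pct.mean()), 0.02, 0.98)
        data[name] = (z[:, k] > norm.ppf(1 - p)).astype(float)

    for name, rate in config.confounder_rates.items():
        data[name] = (rng.random(config.n_subjects) < rate).astype(float)
    data["physical_activity"] = rng.gamma(shape=4.0, scale=25.0,
                                          size=config.n_subjects)

    df = pd.DataFrame({"subject_id": np.arange(1, config.n_subjects + 1),
                       "x": x, "y": y, **{t: data[t] for t in BETA_TERMS[:5]},
                       "dementia": data["dementia"],
                       "physical_activity": data["physical_activity"],
                       "cardiovascular": data["cardiovascular"],
                       "respiratory": data["respiratory"],
                       "alcohol": data["alcohol"],
                       "smoking": data["smoking"]})
    return df


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(cohort: pd.DataFrame, features: pd.DataFrame,
                      config: CityConfig) -> pd.DataFrame:
    """Draw case indicators from the logistic risk model and assign GDS-15.

    The linear predictor uses ``config.true_betas`` on the model's predictor
    scales (binaries 0/1, environmental measures 0-100, activity
    standardised); the intercept is re-calibrated by root-finding so the
    expected prevalence hits ``config.prevalence_target``.  A case draws a
    GDS-15 score uniformly from 8-15, a control from 0-7.
    """
    if len(cohort) != len(features):
        raise ValueError("features are not aligned to cohort rows "
                         f"({len(features)} vs {len(cohort)})")
    rng = config.rng(4)
    out = cohort.copy()
    if len(out) == 0:
        out["gds15"] = np.array([], dtype=float)
        out["case"] = np.array([], dtype=float)
        return out

    X = np.empty((len(out), len(BETA_TERMS)))
    for j, term in enumerate(BETA_TERMS):
        src = features if term in features.columns else out
        X[:, j] = np.asarray(src[term], dtype=float)
    j_act = BETA_TERMS.index("physical_activity")
    sd = X[:, j_act].std()
    if sd > 0:
        X[:, j_act] = (X[:, j_act] - X[:, j_act].mean()) / sd

    eta = X @ config.true_betas[1:]
    if config.prevalence_target is not None:
        target = config.prevalence_target

        def excess(b0: float) -> float:
            return float(np.mean(expit(b0 + eta))) - target

        b0 = brentq(excess, -30.0, 30.0, xtol=1e-10)
    else:
        b0 = float(config.true_betas[0])

    p = expit(b0 + eta)
    case = (rng.random(len(out)) < p).astype(float)
    gds = np.where(case == 1, rng.integers(8, 16, size=len(out)),
                   rng.integers(0, 8, size=len(out)))
    out["gds15"] = gds.astype(float)
    out["case"] = case
    out.attrs["calibrated_intercept"] = b0
    return out


def inject_missing(cohort: pd.DataFrame, config: CityConfig,
                   fields: list[str] | None = None) -> pd.DataFrame:
    """Blank one analysis field in a random ``missing_rate`` fraction of rows."""
    rng = config.rng(5)
    out = cohort.copy()
    n_missing = int(round(config.missing_rate * len(out)))
    if n_missing == 0:
        return out
    fields = fields or [c for c in BETA_TERMS[:5] + ["gds15"] if c in out.columns]
    rows = rng.choice(len(out), size=n_missing, replace=False)
    for r in rows:
        col = fields[int(rng.integers(0, len(fields)))]
        out.loc[out.index[r], col] = np.nan
    return out
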