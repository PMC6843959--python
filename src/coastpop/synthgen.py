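"""Seeded synthetic coastal landscapes for end-to-end testing of the pipeline.

The generator emulates the statistical structure the dasymetric method
assumes, without any real data: a wavy coastline with an elevation ramp
rising inland; settlements (Gaussian intensity blobs) biased toward
low-elevation land; a true population surface whose log density is a noisy
log-linear function of latent covariates plus a settlement term; observed
covariates that are *distorted* versions of the latents (bloomed nighttime
lights, a thresholded settlement footprint, a seasonal NDVI series, slope
derived from the noisy DEM); POI points drawn from an inhomogeneous Poisson
process whose intensity tracks the true population; and a three-level nested
admin partition (province / county / township, Voronoi on seed cells) whose
census counts are exact zonal sums of the true surface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geodata import AdminLayer, GridSpec, Raster, distance_to_coast, slope_from_dem, zonal_aggregate

__all__ = ["SceneConfig", "Scene", "generate_scene", "aggregate_census", "POI_CATEGORY_COUNTS"]

# Category sizes of a published ~2.6M-point national web-map POI inventory
# across its 20 top-level categories; used only as relative per-capita rates.
POI_CATEGORY_COUNTS = (
    192196, 311, 666, 3729, 145049, 39583, 81018, 10873, 6461, 154266,
    20465, 591372, 71622, 380637, 78867, 134506, 492264, 75415, 91065, 7159,
)
_MAINLAND_POP = 1.338e9  # reference population used to turn counts into per-capita rates

def default_poi_rates() -> tuple[float, ...]:
    return tuple(c / _MAINLAND_POP for c in POI_CATEGORY_COUNTS)


def _default_spec() -> GridSpec:
    return GridSpec(512, 512, origin_x=0.0, origin_y=51200.0, cell_size=100.0,
                    crs_tag="synthetic-albers")


@dataclass
class SceneConfig:
    """Knobs of the synthetic world; defaults are the package's study conditions."""

    spec: GridSpec = field(default_factory=_default_spec)
    seed: int = 0
    n_provinces: int = 4
    n_counties: int = 60
    townships_per_county: int = 12
    n_settlements: int = 15
    total_population: float = 5_000_000.0
    # log-density coefficients on the standardised latent covariates, in the
    # order ntl, ndvi, elevation, slope, guf, poi-proxy
    beta: tuple[float, ...] = (0.8, -0.5, -0.6, -0.3, 0.7, 0.8)
    settlement_coef: float = 1.2
    heterogeneity_sd: float = 0.5  # score units; smooth unobserved neighbourhood effects
    ln_density_sd: float = 1.3  # ln-units; spread of the systematic cell log density
    noise_sd: float = 0.3
    poi_rate_per_capita: tuple[float, ...] = field(default_factory=default_poi_rates)
    ntl_blooming_radius: float = 1000.0
    coast_fraction: float = 0.18
    elev_ramp_per_km: float = 1.5  # metres of elevation per km inland
    elev_noise_sd: float = 4.0  # metres, smooth terrain roughness
    guf_threshold: float = 0.12

    def __post_init__(self) -> None:
        for name in ("n_provinces", "n_counties", "townships_per_county", "n_settlements"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.poi_rate_per_capita) != 20:
            raise ValueError("poi_rate_per_capita must have 20 entries")
        if any(r < 0 for r in self.poi_rate_per_capita):
            raise ValueError("poi rates must be >= 0")
        if not 0 < self.coast_fraction < 1:
            raise ValueError("coast_fraction must be in (0, 1)")


@dataclass(eq=False)
class Scene:
    """A generated synthetic study area."""

    config: SceneConfig
    land_mask: Raster
    elevation: Raster
    slope: Raster
    ntl: Raster
    ndvi_series: list  # 36 ten-day composites
    guf: Raster
    true_pop: Raster  # persons per cell
    admin: AdminLayer
    pois: pd.DataFrame  # columns x, y, category (0..19)
    dist_to_coast: Raster

    @property
    def spec(self) -> GridSpec:
        return self.config.spec

    def checksum(self) -> str:
        """SHA-256 digest over every array and table; equal for identical scenes."""
        h = hashlib.sha256()
        for r in (self.land_mask, self.elevation, self.slope, self.ntl, self.guf,
                  self.true_pop, self.admin.labels, self.dist_to_coast, *self.ndvi_series):
            h.update(np.ascontiguousarray(r.values).tobytes())
        h.update(self.pois.to_csv(index=False).encode())
        h.update(self.admin.units.to_csv(index=False).encode())
        return h.hexdigest()


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian random field with unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _zscore(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = a[mask]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - v.mean()) / sd


def generate_scene(config: SceneConfig) -> Scene:
    """Deterministically generate a scene from its config (seeded)."""
    spec = config.spec
    # independent substreams per stage: varying one knob (say noise_sd)
    # perturbs only its own field, leaving terrain, admin and POIs paired
    # across configs (common random numbers)
    streams = {
        name: np.random.default_rng([config.seed, k])
        for k, name in enumerate(
            ("terrain", "settle", "fields", "noise", "obs", "poi", "admin")
        )
    }
    n_r, n_c = spec.shape
    cell_km2 = spec.cell_area_km2

    # --- coastline: sea on the left, wavy boundary ---
    base = config.coast_fraction * n_c
    wiggle = ndimage.gaussian_filter1d(streams['terrain'].standard_normal(n_r), sigma=max(n_r / 16, 1))
    wsd = wiggle.std()
    if wsd > 0:
        wiggle = wiggle / wsd * 0.25 * base
    sea_cols = np.clip(np.round(base + wiggle).astype(int), 1, max(n_c // 2, 2))
    cols = np.arange(n_c)
    land = cols[None, :] >= sea_cols[:, None]
    land_mask = Raster(spec, land.astype(np.uint8), 255)
    n_land = int(land.sum())
    if n_land < config.n_counties:
        raise ValueError("fewer land cells than requested counties")

    # --- elevation: inland ramp + smooth roughness, clipped at sea level ---
    dist = distance_to_coast(Raster(spec, land))
    elev = dist.values * (config.elev_ramp_per_km / 1000.0)
    elev = elev + config.elev_noise_sd * _smooth_noise(streams['terrain'], spec.shape, sigma=8)
    elev = np.clip(elev, 0.0, None)
    elev[~land] = 0.0
    elevation = Raster(spec, elev)
    slope = slope_from_dem(elevation)

    # --- settlements: Gaussian blobs biased toward low elevation ---
    land_idx = np.flatnonzero(land.ravel())
    p = np.exp(-elev.ravel()[land_idx] / 15.0)
    p /= p.sum()
    centers = streams['settle'].choice(land_idx, size=config.n_settlements, replace=False, p=p)
    cr, cc = np.unravel_index(centers, spec.shape)
    amp = streams['settle'].uniform(0.5, 1.5, size=config.n_settlements)
    sigma_m = streams['settle'].uniform(1000.0, 6000.0, size=config.n_settlements)
    rr, cc_grid = np.meshgrid(np.arange(n_r), np.arange(n_c), indexing="ij")
    S = np.zeros(spec.shape)
    for j in range(config.n_settlements):
        d2 = ((rr - cr[j]) ** 2 + (cc_grid - cc[j]) ** 2) * spec.cell_size**2
        S += amp[j] * np.exp(-d2 / (2 * sigma_m[j] ** 2))
    S[~land] = 0.0
    if S.max() > 0:
        S = S / S.max()

    # --- latent covariates and the true log-density surface ---
    veg_base = 0.5 + 0.15 * _smooth_noise(streams['fields'], spec.shape, sigma=10)  # fractional greenness
    ndvi_true = np.clip(veg_base, 0.1, 0.9) * (1.0 - 0.75 * np.clip(S, 0, 1))
    guf_true = (S > config.guf_threshold).astype(float)
    # log-compress the settlement intensity before standardising: urban-core
    # fields (radiance, activity) are log-normal-ish, and an uncompressed
    # z-score would blow the log density up by tens of ln units in the cores
    S_c = np.log1p(63.0 * S)
    amenity = 0.7 * _zscore(S_c, land) + 0.3 * _smooth_noise(streams['fields'], spec.shape, sigma=6)

    latents = (
        _zscore(S_c, land),          # nighttime-light latent (pre-blooming)
        _zscore(ndvi_true, land),
        _zscore(elev, land),
        _zscore(slope.filled(0.0), land),
        _zscore(guf_true, land),
        _zscore(amenity, land),
    )
    score = sum(b * z for b, z in zip(config.beta, latents))
    score = score + config.settlement_coef * _zscore(S_c, land)
    # smooth unobserved neighbourhood effects: spatially correlated structure
    # no covariate can see — the nonstationarity that gives dasymetric mapping
    # its characteristic dense-underestimate / sparse-overestimate bias
    if config.heterogeneity_sd > 0:
        score = score + config.heterogeneity_sd * _smooth_noise(streams['fields'], spec.shape, sigma=12)
    # standardise the systematic score to a realistic log-density spread
    # (published county-level ln densities span roughly 7 ln units, which a
    # cell-level sd near 1.3 reproduces once aggregated), then add the
    # cell-level noise in ln units
    ln_dens = config.ln_density_sd * _zscore(score, land)
    if config.noise_sd > 0:
        ln_dens = ln_dens + streams['noise'].normal(0.0, config.noise_sd, size=spec.shape)
    dens = np.exp(ln_dens)
    dens[~land] = 0.0
    pop = dens / dens.sum() * config.total_population
    true_pop = Raster(spec, pop)

    # --- observed covariates ---
    bloom_sigma = max(config.ntl_blooming_radius / spec.cell_size, 0.1)
    ntl_vals = ndimage.gaussian_filter(S, sigma=bloom_sigma)
    if ntl_vals.max() > 0:
        ntl_vals = ntl_vals / ntl_vals.max()
    ntl_vals = 63.0 * ntl_vals + np.abs(streams['obs'].normal(0.0, 0.3, size=spec.shape))
    ntl = Raster(spec, ntl_vals)

    ndvi_series = []
    t = np.arange(36)
    season = 0.35 + 0.65 * (0.5 + 0.5 * np.sin(2 * np.pi * (t + 1) / 36 - np.pi / 2))
    for k in range(36):
        img = ndvi_true * season[k] + streams['obs'].normal(0.0, 0.02, size=spec.shape)
        img[~land] = -0.1  # open water
        ndvi_series.append(Raster(spec, np.clip(img, -1.0, 1.0)))

    guf = Raster(spec, guf_true)

    # --- POIs: inhomogeneous Poisson, intensity proportional to population ---
    rates = np.asarray(config.poi_rate_per_capita)
    rows_all, cols_all, cats, us, vs = [], [], [], [], []
    for k in range(20):
        lam = rates[k] * pop
        counts = streams['poi'].poisson(lam)
        idx = np.nonzero(counts)
        reps = counts[idx]
        rows_k = np.repeat(idx[0], reps)
        cols_k = np.repeat(idx[1], reps)
        rows_all.append(rows_k)
        cols_all.append(cols_k)
        cats.append(np.full(rows_k.size, k, dtype=int))
        us.append(streams['poi'].random(rows_k.size))
        vs.append(streams['poi'].random(rows_k.size))
    rows_all = np.concatenate(rows_all)
    cols_all = np.concatenate(cols_all)
    pois = pd.DataFrame(
        {
            "x": spec.origin_x + (cols_all + np.concatenate(us)) * spec.cell_size,
            "y": spec.origin_y - (rows_all + np.concatenate(vs)) * spec.cell_size,
            "category": np.concatenate(cats),
        }
    )

    # --- nested admin partition: Voronoi on seed cells, nesting by construction ---
    admin = _make_admin(streams['admin'], spec, land, config)
    admin = aggregate_census(true_pop, admin)

    return Scene(
        config=config,
        land_mask=land_mask,
        elevation=elevation,
        slope=slope,
        ntl=ntl,
        ndvi_series=ndvi_series,
        guf=guf,
        true_pop=true_pop,
        admin=admin,
        pois=pois,
        dist_to_coast=dist,
    )


def _voronoi_assign(points_rc: np.ndarray, seeds_rc: np.ndarray) -> np.ndarray:
    """Index of the nearest seed for each point (ties to the first seed)."""
    tree = cKDTree(seeds_rc)
    _, idx = tree.query(points_rc)
    return idx


def _make_admin(rng: np.random.Generator, spec: GridSpec, land: np.ndarray,
                config: SceneConfig) -> AdminLayer:
    land_rc = np.argwhere(land)
    county_seed_idx = rng.choice(len(land_rc), size=config.n_counties, replace=False)
    county_seeds = land_rc[county_seed_idx]
    county_of_cell = _voronoi_assign(land_rc, county_seeds)

    prov_seed_idx = rng.choice(len(land_rc), size=config.n_provinces, replace=False)
    prov_of_county = _voronoi_assign(county_seeds, land_rc[prov_seed_idx])

    township_labels = np.zeros(spec.shape, dtype=np.int64)
    records = []
    cell_km2 = spec.cell_area_km2
    for p in range(config.n_provinces):
        records.append(dict(unit_id=p + 1, level="province", parent_id=0,
                            census_pop=np.nan, area_km2=0.0))
    next_town = 10001
    for ci in range(config.n_counties):
        county_id = 101 + ci
        cells = land_rc[county_of_cell == ci]
        prov_id = int(prov_of_county[ci]) + 1
        records.append(dict(unit_id=county_id, level="county", parent_id=prov_id,
                            census_pop=np.nan, area_km2=len(cells) * cell_km2))
        if len(cells) == 0:
            continue
        k = min(config.townships_per_county, len(cells))
        tseed_idx = rng.choice(len(cells), size=k, replace=False)
        town_of_cell = _voronoi_assign(cells, cells[tseed_idx])
        for tj in range(k):
            tcells = cells[town_of_cell == tj]
            tid = next_town
            next_town += 1
            township_labels[tcells[:, 0], tcells[:, 1]] = tid
            records.append(dict(unit_id=tid, level="township", parent_id=county_id,
                                census_pop=np.nan, area_km2=len(tcells) * cell_km2))
    units = pd.DataFrame.from_records(records)
    # province areas = sum of member counties
    county_area = units[units["level"] == "county"].set_index("unit_id")["area_km2"]
    for p in range(config.n_provinces):
        members = units[(units["level"] == "county") & (units["parent_id"] == p + 1)]
        units.loc[(units["level"] == "province") & (units["unit_id"] == p + 1),
                  "area_km2"] = members["area_km2"].sum()
    labels = Raster(spec, township_labels, 0)
    return AdminLayer(labels, units)


def aggregate_census(true_pop: Raster, admin: AdminLayer) -> AdminLayer:
    """Set census_pop at every level to the exact zonal sum of ``true_pop``."""
    town_sum = zonal_aggregate(true_pop, admin.label_raster("township"), "sum")
    town_sum = town_sum.fillna(0.0)
    out = admin.with_census(town_sum, "township")
    town_parent = pd.Series(out.parent_map("township"))
    county_sum = town_sum.groupby(town_parent.reindex(town_sum.index)).sum()
    # counties with no townships (no land cells) get 0
    county_ids = out.units_at("county")["unit_id"].astype(int)
    out = out.with_census(county_sum.reindex(county_ids).fillna(0.0), "county")
    cen_county = out.census_at("county")
    parent = out.parent_map("county")
    prov_sum = cen_county.groupby(cen_county.index.map(parent)).sum()
    out = out.with_census(prov_sum, "province")
    return out
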