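"""Model covariate engineering.

Six predictor rasters drive the regression stage: nighttime light, the
annual maximum-value NDVI composite, elevation, slope, the binary settlement
footprint, and a single composite POI density surface (first principal
component of the 20 per-category quartic-kernel densities, bandwidth 2000 m
by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geodata import GridSpec, Raster

__all__ = [
    "KDEParams",
    "CovariateStack",
    "max_composite",
    "kde_density",
    "poi_composite",
    "build_stack",
    "FEATURE_ORDER",
]

log = logging.getLogger(__name__)

FEATURE_ORDER = ("ntl", "ndvi_max", "elevation", "slope", "guf", "poi_den")

N_CATEGORIES = 20


@dataclass(frozen=True)
class KDEParams:
    """Planar kernel density parameters (quartic/biweight kernel)."""

    bandwidth: float = 2000.0  # metres

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


def max_composite(series: list[Raster]) -> Raster:
    """Cell-wise maximum over the series, ignoring nodata; all-nodata -> nodata.

    The standard maximum-value compositing used to build an annual NDVI layer
    that suppresses clouds and seasonal lows.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    spec = series[0].spec
    for r in series[1:]:
        if r.spec != spec:
            raise ValueError("misaligned images in series")
    stack = np.stack([np.where(r.mask(), r.values.astype(float), np.nan) for r in series])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmax(stack, axis=0)
    return Raster(spec, out, float("nan"))


def kde_density(points: pd.DataFrame, category: int, spec: GridSpec,
                params: KDEParams = KDEParams()) -> Raster:
    """Quartic-kernel density surface of one POI category, in points per m².

    At each cell centre x the density is sum_i 3/(pi h^2) (1 - d_i^2/h^2)^2
    over points of the category with d_i = |x - p_i| < h. No boundary
    correction is applied. Cells with no point within h are exactly zero.
    """
    if "category" not in points.columns:
        raise ValueError("points table must have a 'category' column")
    if category not in range(N_CATEGORIES):
        raise ValueError(f"unknown category {category!r}")
    h = params.bandwidth
    sub = points[points["category"] == category]
    out = np.zeros(spec.shape)
    if len(sub) == 0:
        return Raster(spec, out, float("nan"))

    s = spec.cell_size
    norm = 3.0 / (np.pi * h * h)
    reach = int(np.ceil(h / s)) + 1
    row_f, col_f = spec.xy_to_rowcol(sub["x"].values, sub["y"].values)
    for rf, cf in zip(row_f, col_f):
        r0 = max(int(np.floor(rf - reach)), 0)
        r1 = min(int(np.ceil(rf + reach)), spec.n_rows - 1)
        c0 = max(int(np.floor(cf - reach)), 0)
        c1 = min(int(np.ceil(cf + reach)), spec.n_cols - 1)
        if r1 < r0 or c1 < c0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        d2 = ((rows[:, None] - rf) ** 2 + (cols[None, :] - cf) ** 2) * s * s
        u = d2 / (h * h)
        k = np.where(u < 1.0, norm * (1.0 - u) ** 2, 0.0)
        out[r0 : r1 + 1, c0 : c1 + 1] += k
    return Raster(spec, out, float("nan"))


def poi_composite(density_stack: list[Raster]) -> tuple[Raster, float]:
    """First-principal-component composite of per-category density layers.

    Layers are standardised over jointly-valid cells (all-zero/constant layers
    are dropped with a warning); the first component score is computed per
    cell and sign-oriented to correlate non-negatively with the mean of the
    standardised layers. Returns (composite raster, explained-variance
    fraction of the first component).
    """
    if len(density_stack) < 2:
        raise ValueError("need at least two density layers")
    spec = density_stack[0].spec
    for r in density_stack[1:]:
        if r.spec != spec:
            raise ValueError("misaligned density layers")
    valid = np.ones(spec.shape, dtype=bool)
    for r in density_stack:
        valid &= r.mask()

    cols = []
    for i, r in enumerate(density_stack):
        v = r.values.astype(float)[valid]
        if v.std() == 0:
            log.warning("dropping degenerate (constant) density layer %d", i)
            continue
        cols.append(v)
    if len(cols) < 2:
        raise ValueError("fewer than two non-degenerate density layers")
    X = np.column_stack(cols)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)

    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    evr = float(pca.explained_variance_ratio_[0])
    # orient so the component tracks overall density positively
    ref = Z.mean(axis=1)
    if np.dot(scores - scores.mean(), ref) < 0:
        scores = -scores
    out = np.full(spec.shape, np.nan)
    out[valid] = scores
    return Raster(spec, out, float("nan")), evr


@dataclass(eq=False)
class CovariateStack:
    """The six aligned predictor rasters plus provenance metadata."""

    layers: dict[str, Raster]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_ORDER if n not in self.layers]
        if missing:
            raise ValueError(f"missing covariate layers: {missing}")
        spec = self.spec
        for name, r in self.layers.items():
            if r.spec != spec:
                raise ValueError(f"layer {name!r} not aligned to the stack grid")

    @property
    def spec(self) -> GridSpec:
        return self.layers[FEATURE_ORDER[0]].spec

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_ORDER

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.spec.shape, dtype=bool)
        for name in FEATURE_ORDER:
            m &= self.layers[name].mask()
        return m

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Feature matrix (n_cells, 6) over ``mask`` (default: jointly valid cells)."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack(
            [self.layers[n].values.astype(float)[mask] for n in FEATURE_ORDER]
        )

    def drop_poi(self) -> "CovariateStack":
        """Ablation variant: POI density replaced by an all-zero layer."""
        layers = dict(self.layers)
        layers["poi_den"] = Raster(self.spec, np.zeros(self.spec.shape), float("nan"))
        meta = dict(self.meta, poi_ablated=True)
        return CovariateStack(layers, meta)


def build_stack(scene, params: KDEParams = KDEParams(),
                include_poi: bool = True) -> CovariateStack:
    """Assemble the six-covariate stack from a scene.

    NDVI is the Eq.-style annual max composite of the 10-day series; POI
    density is the first-PC composite of the 20 per-category KDE surfaces.
    Layer order is fixed (``FEATURE_ORDER``) so feature names are stable.
    """
    spec = scene.spec
    ndvi_max = max_composite(scene.ndvi_series)
    meta: dict = {"kde_bandwidth_m": params.bandwidth, "feature_order": list(FEATURE_ORDER)}

    if include_poi and len(scene.pois) > 0:
        dens = [kde_density(scene.pois, k, spec, params) for k in range(N_CATEGORIES)]
        n_degenerate = sum(1 for d in dens if d.valid_values().std() == 0)
        if len(dens) - n_degenerate >= 2:
            poi_den, evr = poi_composite(dens)
            # restrict to land; sea carries no density signal
            vals = poi_den.values.copy()
            meta["pca_explained_variance_fraction"] = evr
        else:
            log.warning("POI densities degenerate; using all-zero POI layer")
            vals = np.zeros(spec.shape)
            meta["pca_explained_variance_fraction"] = None
        poi_layer = Raster(spec, vals, float("nan"))
    else:
        log.warning("building stack without POI information (ablation path)")
        poi_layer = Raster(spec, np.zeros(spec.shape), float("nan"))
        meta["pca_explained_variance_fraction"] = None
        meta["poi_ablated"] = True

    layers = {
        "ntl": scene.ntl,
        "ndvi_max": ndvi_max,
        "elevation": scene.elevation,
        "slope": scene.slope,
        "guf": scene.guf,
        "poi_den": poi_layer,
    }
    return CovariateStack(layers, meta)
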