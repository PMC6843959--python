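"""Low-elevation coastal zone extraction and exposure accounting.

The LECZ is the coastal land below an elevation threshold (default 10 m)
and within a distance threshold of the coastline (default 100 km), both
strict inequalities. Exposure tables report, per admin region, the
population inside the zone, the region total, and the percentage exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dasymetric import PopulationGrid
from .geodata import AdminLayer, Raster

__all__ = ["LECZParams", "extract_lecz", "exposure_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LECZParams:
    elev_threshold: float = 10.0  # metres
    dist_threshold: float = 100_000.0  # metres
    require_coast_connectivity: bool = False

    def __post_init__(self) -> None:
        if not (self.elev_threshold > 0 and self.dist_threshold > 0):
            raise ValueError("thresholds must be positive")


def extract_lecz(dem: Raster, dist: Raster, land_mask: Raster,
                 params: LECZParams = LECZParams()) -> Raster:
    """Boolean LECZ mask: land, elevation < threshold, distance < threshold.

    Nodata DEM cells are excluded (and logged). With the connectivity flag
    on, only 8-connected components touching the coast are kept — the
    'contiguous area along the coast' reading of the zone definition.
    """
    if dem.spec != dist.spec or dem.spec != land_mask.spec:
        raise ValueError("dem, distance and land rasters are not aligned")
    land = land_mask.values.astype(bool)
    dem_ok = dem.mask()
    n_bad = int((land & ~dem_ok).sum())
    if n_bad:
        log.warning("excluding %d land cells with nodata elevation from the LECZ", n_bad)
    with np.errstate(invalid="ignore"):
        mask = (
            land
            & dem_ok
            & (dem.values.astype(float) < params.elev_threshold)
            & (dist.values.astype(float) < params.dist_threshold)
        )
    if params.require_coast_connectivity and mask.any():
        structure = np.ones((3, 3), dtype=bool)
        comp, _ = ndimage.label(mask, structure=structure)
        sea = ~land
        coast_ring = ndimage.binary_dilation(sea, structure=structure) & land
        keep = np.unique(comp[mask & coast_ring])
        keep = keep[keep != 0]
        mask = np.isin(comp, keep) & mask
    return Raster(dem.spec, mask.astype(np.uint8), 255)


def exposure_table(pop: PopulationGrid, mask: Raster, admin: AdminLayer,
                   level: str = "province") -> pd.DataFrame:
    """Per-region exposed population, total population and percentage, plus a
    global 'total' row. Regions with zero total get NaN percentage."""
    labels = admin.label_raster(level)
    if pop.raster.spec != mask.spec or pop.raster.spec != labels.spec:
        raise ValueError("population, mask and admin layers are not aligned")
    lab = labels.values.astype(np.int64)
    p = pop.raster.filled(0.0)
    m = mask.values.astype(bool)

    n = int(lab.max()) + 1
    total = np.bincount(lab.ravel(), weights=p.ravel(), minlength=n)
    exposed = np.bincount(lab[m].ravel(), weights=p[m].ravel(), minlength=n)

    ids = np.unique(lab)
    ids = ids[ids != 0]
    rows = []
    for uid in ids:
        t, e = total[uid], exposed[uid]
        pct = 100.0 * e / t if t > 0 else np.nan
        rows.append(dict(region_id=int(uid), exposed_pop=e, total_pop=t, pct_exposed=pct))
    te, tt = exposed[ids].sum(), total[ids].sum()
    rows.append(dict(region_id=0, exposed_pop=te, total_pop=tt,
                     pct_exposed=100.0 * te / tt if tt > 0 else np.nan))
    return pd.DataFrame(rows)
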