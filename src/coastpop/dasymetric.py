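"""Mass-preserving dasymetric redistribution of census counts to the grid.

The fitted log-density prediction layer becomes a per-cell weight surface W;
each census unit's count is then spread over its cells as

    POP_grid = POP_unit * W_grid / W_unit,   W_unit = sum of W over the unit,

so unit totals are preserved exactly (up to float rounding). Two weight
modes are offered: ``exp`` back-transforms the ln-density prediction to the
density scale before weighting (standard dasymetric practice), ``raw`` uses
the ln-scale prediction directly, clipped at zero — the behaviour implied
when published weight-layer ranges coincide with ln-prediction ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateStack
from .geodata import AdminLayer, Raster, zonal_aggregate
from .regressors import TrainingTable

__all__ = [
    "WeightRaster",
    "PopulationGrid",
    "build_training_table",
    "weights_from_prediction",
    "redistribute",
]

log = logging.getLogger(__name__)


@dataclass(eq=False)
class WeightRaster:
    """Non-negative per-cell allocation weights plus the valid-cell mask."""

    raster: Raster  # weights; 0 where invalid
    mode: str  # "exp" | "raw"
    valid: np.ndarray  # boolean: cells eligible to receive population


@dataclass(eq=False)
class PopulationGrid:
    """Persons per grid cell, conserving the driving census level."""

    raster: Raster
    level: str


def build_training_table(stack: CovariateStack, admin: AdminLayer,
                         level: str = "county") -> TrainingTable:
    """Zonal-mean covariates and y = ln(census density) per admin unit.

    Units with zero census population or any flagged-missing zonal mean are
    dropped (counted in the returned table's ``n_dropped_*`` fields).
    """
    labels = admin.label_raster(level)
    units = admin.units_at(level).set_index("unit_id")
    if units["census_pop"].isna().all():
        raise ValueError(f"census counts absent at level {level!r}")

    feats = {}
    for name in stack.feature_names:
        feats[name] = zonal_aggregate(stack.layers[name], labels, "mean")
    table = pd.DataFrame(feats)
    table["census_pop"] = units["census_pop"].reindex(table.index)
    table["area_km2"] = units["area_km2"].reindex(table.index)

    n0 = len(table)
    missing = table[list(stack.feature_names)].isna().any(axis=1)
    zero = ~(table["census_pop"] > 0)
    n_missing = int(missing.sum())
    n_zero = int((zero & ~missing).sum())
    if n_missing:
        log.warning("dropping %d %s units with missing zonal covariates", n_missing, level)
    if n_zero:
        log.warning("dropping %d %s units with zero census population", n_zero, level)
    table = table[~missing & ~zero]
    if len(table) == 0:
        raise ValueError("no usable training units")

    frame = table.reset_index()[["unit_id", *stack.feature_names]].copy()
    frame["y"] = np.log(table["census_pop"].values / table["area_km2"].values)
    return TrainingTable(
        frame=frame,
        feature_names=stack.feature_names,
        n_dropped_zero_pop=n_zero,
        n_dropped_missing=n_missing,
    )


def weights_from_prediction(pred: Raster, mode: str = "exp") -> WeightRaster:
    """Turn a ln-density prediction raster into allocation weights."""
    if mode not in ("exp", "raw"):
        raise ValueError(f"unknown weight mode {mode!r}")
    valid = pred.mask()
    vals = pred.values.astype(float)
    if np.isneginf(vals[valid]).any():
        raise ValueError("prediction contains -inf")
    if mode == "exp":
        w = np.where(valid, np.exp(vals), 0.0)
    else:
        w = np.where(valid, np.clip(vals, 0.0, None), 0.0)
    return WeightRaster(Raster(pred.spec, w, float("nan")), mode, valid)


def redistribute(W: WeightRaster, admin: AdminLayer, level: str = "county") -> PopulationGrid:
    """Spread each unit's census count over its valid cells proportionally to W.

    A unit whose weights sum to zero falls back to uniform allocation over its
    valid cells (logged); a unit with census > 0 but no valid cell is an error.
    """
    labels = admin.label_raster(level)
    if labels.spec != W.raster.spec:
        raise ValueError("weight raster and admin labels are not aligned")
    census = admin.census_at(level)
    if census.isna().all():
        raise ValueError(f"census counts absent at level {level!r}")

    lab = labels.values.astype(np.int64)
    w = np.where(W.valid, W.raster.values.astype(float), 0.0)
    n = int(lab.max()) + 1
    w_sum = np.bincount(lab.ravel(), weights=w.ravel(), minlength=n)
    valid_cnt = np.bincount(lab[W.valid].ravel(), minlength=n)

    pop = np.zeros(labels.spec.shape)
    for uid, pop_u in census.items():
        uid = int(uid)
        if not np.isfinite(pop_u) or pop_u == 0:
            continue
        in_unit = lab == uid
        if valid_cnt[uid] == 0:
            raise ValueError(f"unit {uid} has census {pop_u} but no valid cells")
        if w_sum[uid] > 0:
            pop[in_unit] = pop_u * w[in_unit] / w_sum[uid]
        else:
            log.warning("unit %d has all-zero weights; falling back to uniform allocation", uid)
            uniform = in_unit & W.valid
            pop[uniform] = pop_u / valid_cnt[uid]
    return PopulationGrid(Raster(labels.spec, pop, float("nan")), level)
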