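"""Statsmodels-style facade over the mapping pipeline.

:class:`PopulationModel` is built from data (a covariate stack plus an admin
layer carrying county censuses, usually via :meth:`PopulationModel.from_scene`);
``fit`` trains the chosen regression engine on the county training table,
predicts the ln-density surface, turns it into allocation weights and
redistributes the census — returning a :class:`PopulationResults` that
carries the estimates, diagnostics and a ``summary()`` table, with
validation, exposure accounting and plotting hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack, KDEParams, build_stack
from .dasymetric import (PopulationGrid, WeightRaster, build_training_table,
                         redistribute, weights_from_prediction)
from .geodata import AdminLayer, Raster, zonal_aggregate
from .lecz import LECZParams, exposure_table, extract_lecz
from .regressors import (FittedModel, TrainingTable, fit_m5, fit_rf,
                         permutation_importance, predict_raster)

__all__ = ["PopulationModel", "PopulationResults"]


class PopulationModel:
    """Dasymetric population-mapping model.

    Parameters
    ----------
    stack : CovariateStack
        The six aligned predictor rasters.
    admin : AdminLayer
        Nested admin units with census counts at the training level.
    land_mask : Raster, optional
        Restricts the allocation domain to land; without it every jointly
        valid covariate cell may receive population.
    regressor : {"rf", "m5"}
        Bagged-tree ensemble or M5-style model tree ("cubist" is accepted as
        an alias for "m5").
    weight_mode : {"exp", "raw"}
        Back-transform ln-density predictions before weighting, or use the
        ln-scale values directly (clipped at zero).
    """

    def __init__(self, stack: CovariateStack, admin: AdminLayer,
                 land_mask: Raster | None = None, regressor: str = "rf",
                 weight_mode: str = "exp", train_level: str = "county",
                 n_trees: int = 500, mtry: int | None = None, min_leaf: int = 4,
                 scene=None):
        if regressor == "cubist":
            regressor = "m5"
        if regressor not in ("rf", "m5"):
            raise ValueError(f"unknown regressor {regressor!r}")
        if weight_mode not in ("exp", "raw"):
            raise ValueError(f"unknown weight mode {weight_mode!r}")
        self.stack = stack
        self.admin = admin
        self.land_mask = land_mask
        self.regressor = regressor
        self.weight_mode = weight_mode
        self.train_level = train_level
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.scene = scene

    @classmethod
    def from_scene(cls, scene, kde_params: KDEParams = KDEParams(),
                   include_poi: bool = True, **kwargs) -> "PopulationModel":
        """Build the model from a synthetic scene (covariates engineered here)."""
        stack = build_stack(scene, params=kde_params, include_poi=include_poi)
        return cls(stack, scene.admin, land_mask=scene.land_mask, scene=scene, **kwargs)

    def fit(self, seed: int = 0) -> "PopulationResults":
        """Train the engine, predict the weight surface, redistribute the census."""
        table = build_training_table(self.stack, self.admin, self.train_level)
        if self.regressor == "rf":
            fitted = fit_rf(table, n_trees=self.n_trees, mtry=self.mtry, seed=seed)
        else:
            fitted = fit_m5(table, min_leaf=self.min_leaf)
        domain = None
        if self.land_mask is not None:
            domain = self.land_mask.values.astype(bool)
        prediction = predict_raster(fitted, self.stack, domain=domain)
        weights = weights_from_prediction(prediction, mode=self.weight_mode)
        population = redistribute(weights, self.admin, level=self.train_level)
        return PopulationResults(
            model=self,
            table=table,
            fitted=fitted,
            prediction=prediction,
            weights=weights,
            population=population,
            seed=seed,
        )


@dataclass(eq=False)
class PopulationResults:
    """Results of a fitted dasymetric mapping run."""

    model: PopulationModel
    table: TrainingTable
    fitted: FittedModel
    prediction: Raster
    weights: WeightRaster
    population: PopulationGrid
    seed: int
    _importance: pd.DataFrame | None = field(default=None, repr=False)

    # -- diagnostics --------------------------------------------------------

    def conservation_error(self) -> float:
        """Max relative |grid sum − census| over training-level units with census > 0."""
        level = self.model.train_level
        sums = zonal_aggregate(self.population.raster,
                               self.model.admin.label_raster(level), "sum").fillna(0.0)
        census = self.model.admin.census_at(level)
        census = census[census > 0]
        rel = np.abs(sums.reindex(census.index).fillna(0.0) - census) / census
        return float(rel.max())

    def prediction_range(self) -> tuple[float, float]:
        v = self.prediction.valid_values()
        return float(np.min(v)), float(np.max(v))

    def importance(self, n_repeats: int = 10, seed: int | None = None) -> pd.DataFrame:
        """Feature importance: %IncMSE (ensemble) or VarImp % (model tree)."""
        if self.fitted.kind == "rf":
            if self._importance is None:
                self._importance = permutation_importance(
                    self.fitted, self.table, n_repeats=n_repeats,
                    seed=self.seed if seed is None else seed,
                )
            return self._importance
        return self.fitted.importance

    # -- validation and exposure -------------------------------------------

    def evaluate(self, level: str = "township"):
        from .evaluation import evaluate
        return evaluate(self.population, self.model.admin, level=level)

    def stratified(self, level: str = "township"):
        from .evaluation import stratified_report
        return stratified_report(self.population, self.model.admin, level=level)

    def exposure(self, params: LECZParams = LECZParams(), level: str = "province",
                 dem: Raster | None = None, dist: Raster | None = None,
                 land_mask: Raster | None = None) -> pd.DataFrame:
        """LECZ exposure table; DEM/distance/land default to the scene's."""
        scene = self.model.scene
        if dem is None or dist is None or land_mask is None:
            if scene is None:
                raise ValueError("provide dem, dist and land_mask (no scene attached)")
            dem = dem or scene.elevation
            dist = dist or scene.dist_to_coast
            land_mask = land_mask or scene.land_mask
        mask = extract_lecz(dem, dist, land_mask, params)
        return exposure_table(self.population, mask, self.model.admin, level=level)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Dasymetric population mapping results",
            "=" * 46,
            f"engine:            {'bagged-tree ensemble' if self.fitted.kind == 'rf' else 'M5 model tree'}",
            f"weight mode:       {m.weight_mode}",
            f"training level:    {m.train_level} ({len(self.table)} units"
            f", {self.table.n_dropped_zero_pop + self.table.n_dropped_missing} dropped)",
            f"ln-density target: [{self.fitted.y_min:.3f}, {self.fitted.y_max:.3f}]",
        ]
        lo, hi = self.prediction_range()
        lines.append(f"prediction range:  [{lo:.3f}, {hi:.3f}]")
        if self.fitted.oob_mse is not None:
            lines.append(f"OOB MSE:           {self.fitted.oob_mse:.4f}")
        if self.fitted.kind == "m5" and self.fitted.rules is not None:
            lines.append(f"rules:             {len(self.fitted.rules)}")
        lines.append(f"conservation err:  {self.conservation_error():.2e} (max rel., {m.train_level})")
        imp = self.importance()
        if imp is not None:
            col = imp.columns[1]
            lines.append("")
            lines.append(f"importance ({col}):")
            for _, row in imp.sort_values(col, ascending=False).iterrows():
                lines.append(f"  {row['feature']:<10s} {row[col]:8.2f}")
        return "\n".join(lines)

    def plot_map(self, ax=None, log_scale: bool = True):
        """Imshow of the predicted population surface (persons per cell)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.population.raster.filled(0.0)
        img = np.log10(vals + 1.0) if log_scale else vals
        im = ax.imshow(img, cmap="magma")
        ax.set_title("predicted population" + (" (log10 persons/cell + 1)" if log_scale else ""))
        plt.colorbar(im, ax=ax, shrink=0.8)
        return ax

    def plot_validation(self, level: str = "township", ax=None):
        """Log-log scatter of predicted vs census unit densities, coloured by
        the 20/60/20 density strata."""
        import matplotlib.pyplot as plt

        from .evaluation import _unit_frame

        if ax is None:
            _, ax = plt.subplots()
        df = _unit_frame(self.population, self.model.admin, level)
        df = df[(df["census"] > 0) & (df["pred"] > 0)]
        dens_c = df["census"] / df["area_km2"]
        dens_p = df["pred"] / df["area_km2"]
        q_lo, q_hi = np.quantile(dens_c, (0.2, 0.8))
        colors = np.where(dens_c <= q_lo, "tab:blue",
                          np.where(dens_c <= q_hi, "tab:green", "tab:red"))
        ax.scatter(np.log10(dens_c), np.log10(dens_p), s=6, c=colors, alpha=0.6)
        lims = [min(ax.get_xlim()[0], ax.get_ylim()[0]), max(ax.get_xlim()[1], ax.get_ylim()[1])]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("log10 census density")
        ax.set_ylabel("log10 predicted density")
        return ax
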