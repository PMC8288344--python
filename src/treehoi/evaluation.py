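"""Kernel-grid search, information criteria and repeated k-fold CV.

The kernel exponents (u, v) are not fitted jointly with the regression
coefficients: the term sums are recomputed on a grid of (u, v) for each
maximum radius R, every model class is refitted per cell, and the optimum is
the log-likelihood maximiser (which coincides with the R^2 maximiser: exactly
for OLS, and under McFadden's pseudo-R^2 — a monotone transform of the
likelihood — for the logistic).  Model classes are then compared at their own
optima by AIC, BIC and repeated k-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .census import CensusPlot, GroupingScheme, assign_groups
from .interactions import KernelParams, build_neighbour_graph, terms_batch
from .models import (FitError, FitResult, build_design, fit_growth,
                     fit_survival, fit_model, normalize_model_class)

logger = logging.getLogger("treehoi")

DEFAULT_SHAPE_VALUES = tuple(np.round(np.arange(0, 2.0001, 0.1), 10))


@dataclass(frozen=True)
class GridSpec:
    """The (R, u, v) sweep; defaults give the 3 x 21 x 21 = 1323-case grid."""

    radii: tuple = (10.0, 20.0, 30.0)
    u_values: tuple = DEFAULT_SHAPE_VALUES
    v_values: tuple = DEFAULT_SHAPE_VALUES

    def __post_init__(self):
        for name in ("radii", "u_values", "v_values"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(x) for x in vals))
            vals = getattr(self, name)
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be sorted ascending")
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return len(self.radii) * len(self.u_values) * len(self.v_values)


@dataclass
class GridSearchResult:
    """Optimum (u, v) at one radius, the refit there, and the full surface."""

    radius: float
    u_opt: float
    v_opt: float
    fit: FitResult
    cells: pd.DataFrame            # columns u, v, loglik, r2, ok
    r2_argmax_agrees: bool


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) = (2k - 2*loglik, k*ln(n) - 2*loglik)."""
    if fit.n <= 0:
        raise ValueError("sample count must be positive")
    aic = 2 * fit.k - 2 * fit.loglik
    bic = fit.k * np.log(fit.n) - 2 * fit.loglik
    return float(aic), float(bic)


def _argmax_small_uv(cells: pd.DataFrame, col: str):
    """Row index of the maximum of ``col``, ties broken toward smaller (u, v)."""
    ok = cells[cells["ok"]]
    if ok.empty:
        raise FitError("every grid cell failed to fit")
    best = ok[col].max()
    winners = ok[np.isclose(ok[col], best, rtol=0, atol=0) | (ok[col] == best)]
    winners = winners.sort_values(["u", "v"])
    return winners.index[0]


def grid_search(plot: CensusPlot, grouping: GroupingScheme | None,
                response: str, model_class: str, grid: GridSpec,
                focal_group: str, min_increment: float = 0.0,
                allow_focal_initiator: bool = False) -> dict:
    """Sweep (u, v) per radius and return the log-likelihood maximiser.

    The SIZE class has no (u, v) and is rejected.  Cells whose fit fails
    (separation at extreme exponents, rank deficiency) are flagged and
    excluded from the argmax.  Returns {radius: GridSearchResult}.
    """
    mc = normalize_model_class(model_class)
    if mc == "SIZE":
        raise ValueError("the SIZE class has no kernel exponents to optimise")
    if grouping is not None:
        plot = assign_groups(plot, grouping)
    results: dict = {}
    for R in grid.radii:
        graph = build_neighbour_graph(plot, R)
        rows, fits = [], {}
        for u in grid.u_values:
            for v in grid.v_values:
                params = KernelParams(u=u, v=v, R=R)
                terms = terms_batch(plot, params, focal_group, graph=graph,
                                    allow_focal_initiator=allow_focal_initiator)
                try:
                    fit = fit_model(terms, plot, response, mc,
                                    focal_group=focal_group,
                                    min_increment=min_increment)
                    rows.append({"u": u, "v": v, "loglik": fit.loglik,
                                 "r2": fit.r2, "ok": True})
                    fits[(u, v)] = fit
                except FitError as exc:
                    logger.warning("grid cell (u=%.2f, v=%.2f, R=%g) failed: %s",
                                   u, v, R, exc)
                    rows.append({"u": u, "v": v, "loglik": np.nan,
                                 "r2": np.nan, "ok": False})
        cells = pd.DataFrame(rows)
        i_ll = _argmax_small_uv(cells, "loglik")
        i_r2 = _argmax_small_uv(cells, "r2")
        u_opt, v_opt = float(cells.at[i_ll, "u"]), float(cells.at[i_ll, "v"])
        results[R] = GridSearchResult(
            radius=R, u_opt=u_opt, v_opt=v_opt, fit=fits[(u_opt, v_opt)],
            cells=cells, r2_argmax_agrees=bool(i_ll == i_r2))
    return results


def repeated_kfold_cv(plot: CensusPlot, terms: pd.DataFrame, response: str,
                      model_class: str, folds: int = 10, repeats: int = 10,
                      seed: int = 0, min_increment: float = 0.0
                      ) -> tuple[float, float]:
    """Pooled out-of-sample (RMSE, MAE) over ``repeats`` reshuffled k-folds.

    Survival folds are stratified by outcome (deaths are rare; an
    unstratified fold can contain no deaths and break the held-out refit);
    growth folds are plain shuffled k-folds.  Survival errors are predicted
    probability minus the 0/1 outcome; growth errors are on the natural
    increment scale (cm).  Deterministic for a fixed seed.
    """
    mc = normalize_model_class(model_class)
    X, y = build_design(terms, plot, response, mc, min_increment)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    Xv, yv = X.reset_index(drop=True), y.reset_index(drop=True)
    sq_err, abs_err = [], []
    rng = np.random.SeedSequence(seed)
    for rep_seed in rng.generate_state(repeats):
        rs = int(rep_seed % (2 ** 31))
        if response == "survival":
            splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                       random_state=rs)
            split_iter = splitter.split(Xv, yv)
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(Xv)
        for train, test in split_iter:
            fitter = fit_survival if response == "survival" else fit_growth
            fit = fitter(Xv.iloc[train], yv.iloc[train])
            eta = (Xv.iloc[test].to_numpy(float)
                   @ fit.params.to_numpy(float))
            if response == "survival":
                from scipy.special import expit
                err = expit(eta) - yv.iloc[test].to_numpy(float)
            else:
                err = np.exp(eta) - np.exp(yv.iloc[test].to_numpy(float))
            sq_err.append(err ** 2)
            abs_err.append(np.abs(err))
    sq = np.concatenate(sq_err)
    ab = np.concatenate(abs_err)
    return float(np.sqrt(sq.mean())), float(ab.mean())


def comparison_table(plot: CensusPlot, grouping: GroupingScheme | None,
                     grid: GridSpec, folds: int = 10, repeats: int = 10,
                     seed: int = 0, min_increment: float = 0.0,
                     responses: tuple = ("survival", "growth"),
                     focal_groups: tuple | None = None,
                     meaningful_gap: float = 2.0) -> pd.DataFrame:
    """Per radius x focal group x response, the three model-class rows.

    Each SIZE+DI and SIZE+DI+HOI row is evaluated at its own grid-optimum
    (u, v); SIZE has none.  Columns mirror the standard comparison layout
    (k, n, r2, loglik, aic, bic, rmse, mae) plus winner flags: ``best_<ic>``
    marks the class minimising the criterion, and ``meaningful_<ic>`` marks a
    gap of at least ``meaningful_gap`` (default 2) to the runner-up, the
    conventional threshold for a real improvement in parsimony.
    """
    if grouping is not None:
        plot = assign_groups(plot, grouping)
    if focal_groups is None:
        focal_groups = tuple(plot.groups)
    rows = []
    for R in grid.radii:
        for g in focal_groups:
            for response in responses:
                opt = {}
                for mc in ("SIZE_DI", "SIZE_DI_HOI"):
                    res = grid_search(
                        plot, None, response, mc,
                        GridSpec(radii=(R,), u_values=grid.u_values,
                                 v_values=grid.v_values),
                        focal_group=g, min_increment=min_increment)[R]
                    opt[mc] = res
                for mc in ("SIZE", "SIZE_DI", "SIZE_DI_HOI"):
                    if mc == "SIZE":
                        # (u, v) is immaterial for SIZE; reuse the SIZE+DI
                        # optimum's term table to carry ids and fates.
                        src = opt["SIZE_DI"]
                        terms = terms_batch(
                            plot, KernelParams(src.u_opt, src.v_opt, R),
                            focal_group=g)
                        fit = fit_model(terms, plot, response, mc,
                                        focal_group=g,
                                        min_increment=min_increment)
                        u_opt = v_opt = np.nan
                    else:
                        src = opt[mc]
                        fit = src.fit
                        u_opt, v_opt = src.u_opt, src.v_opt
                        terms = terms_batch(
                            plot, KernelParams(u_opt, v_opt, R),
                            focal_group=g)
                    aic, bic = information_criteria(fit)
                    rmse, mae = repeated_kfold_cv(
                        plot, terms, response, mc, folds=folds,
                        repeats=repeats, seed=seed,
                        min_increment=min_increment)
                    rows.append({
                        "radius": R, "group": g, "response": response,
                        "model_class": mc, "u_opt": u_opt, "v_opt": v_opt,
                        "k": fit.k, "n": fit.n, "r2": fit.r2,
                        "loglik": fit.loglik, "aic": aic, "bic": bic,
                        "rmse": rmse, "mae": mae})
    table = pd.DataFrame(rows)
    for crit in ("aic", "bic", "rmse", "mae"):
        table[f"best_{crit}"] = False
        table[f"meaningful_{crit}"] = False
    for _, block in table.groupby(["radius", "group", "response"]):
        for crit in ("aic", "bic", "rmse", "mae"):
            order = block[crit].sort_values()
            i_best = order.index[0]
            table.at[i_best, f"best_{crit}"] = True
            if crit in ("aic", "bic") and len(order) > 1:
                gap = order.iloc[1] - order.iloc[0]
                table.at[i_best, f"meaningful_{crit}"] = bool(
                    gap >= meaningful_gap)
    return table
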