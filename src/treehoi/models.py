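"""Survival and growth models with DI/HOI neighbourhood covariates.

Three nested model classes per response and focal species:

* SIZE           — tree size only,
* SIZE+DI        — size plus one direct term per neighbour group,
* SIZE+DI+HOI    — size, direct terms, and one higher-order term per ordered
                   group pair.

Survival is a logistic regression on the linear predictor
eta = lambda_i + g1*DBH^-1 + g2*DBH + g3*DBH^2 + sum_j a_ij*di_j
      + sum_jk b_ijk*hoi_jk, with P(survive) = 1/(1+exp(-eta)) so that a
negative (competitive) alpha lowers survival.  Growth is multiplicative,
Growth = G_pot * DBH^gamma * exp(DI) * exp(HOI); its log-transform is fitted
by ordinary least squares on survivors with a positive DBH increment.
Each focal species (group) is fitted in its own model, so the intercept is
the species-specific lambda_i / ln G_pot,i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .census import CensusPlot
from .interactions import di_column_names, hoi_column_names

logger = logging.getLogger("treehoi")

MODEL_CLASSES = ("SIZE", "SIZE_DI", "SIZE_DI_HOI")
MAX_ITER = 100
LOGLIK_RTOL = 1e-8

SURVIVAL_SIZE_COLS = ["intercept", "inv_dbh", "dbh", "dbh2"]
GROWTH_SIZE_COLS = ["intercept", "log_dbh"]


class FitError(RuntimeError):
    """Model fitting failed (separation, non-convergence, rank deficiency)."""


def normalize_model_class(model_class: str) -> str:
    mc = model_class.upper().replace("+", "_").replace(" ", "")
    if mc not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}; "
                         f"expected one of {MODEL_CLASSES}")
    return mc


@dataclass
class SurvivalCoefficients:
    """Named view of a fitted survival model's coefficients."""

    lambda_i: float
    gamma1: float
    gamma2: float
    gamma3: float
    alpha: dict | None = None       # group j -> alpha_ij
    beta: dict | None = None        # (j, k) -> beta_ij,k


@dataclass
class GrowthCoefficients:
    """Named view of a fitted growth model's coefficients (natural scale)."""

    g_pot: float                    # exp(intercept), cm per census interval
    gamma: float
    alpha: dict | None = None
    beta: dict | None = None


@dataclass
class FitResult:
    """One fitted model: coefficients, likelihood and bookkeeping."""

    response: str                   # "survival" | "growth"
    model_class: str
    params: pd.Series               # raw linear-predictor coefficients
    bse: pd.Series                  # standard errors
    loglik: float
    k: int                          # free linear parameters (Table-style count)
    n: int
    r2: float                       # McFadden pseudo-R2 / OLS R2
    kernel: dict                    # {"u": .., "v": .., "R": ..}
    groups: list
    focal_group: str | None = None

    @property
    def coefficients(self):
        p = self.params
        alpha = beta = None
        di_cols = [c for c in p.index if c.startswith("di_")]
        hoi_cols = [c for c in p.index if c.startswith("hoi_")]
        if di_cols:
            alpha = {c[len("di_"):]: p[c] for c in di_cols}
        if hoi_cols:
            # group labels themselves must not contain "_"
            beta = {tuple(c[len("hoi_"):].split("_", 1)): p[c] for c in hoi_cols}
        if self.response == "survival":
            return SurvivalCoefficients(
                lambda_i=p["intercept"], gamma1=p["inv_dbh"],
                gamma2=p["dbh"], gamma3=p["dbh2"], alpha=alpha, beta=beta)
        return GrowthCoefficients(
            g_pot=float(np.exp(p["intercept"])), gamma=p["log_dbh"],
            alpha=alpha, beta=beta)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def to_dict(self) -> dict:
        return {"response": self.response, "model_class": self.model_class,
                "kernel": self.kernel, "focal_group": self.focal_group,
                "coefficients": {k: float(v) for k, v in self.params.items()},
                "loglik": float(self.loglik), "k": int(self.k),
                "n": int(self.n), "r2": float(self.r2)}


def _merge_terms(terms: pd.DataFrame, plot: CensusPlot) -> pd.DataFrame:
    tab = terms.merge(plot.trees, left_on="focal_id", right_on="id",
                      how="left", validate="one_to_one")
    if tab["dbh0"].isna().any():
        missing = tab.loc[tab["dbh0"].isna(), "focal_id"].tolist()[:5]
        raise ValueError(f"terms reference unknown tree ids, e.g. {missing}")
    return tab


def build_covariates(terms: pd.DataFrame, plot: CensusPlot, response: str,
                     model_class: str) -> pd.DataFrame:
    """Design-matrix columns (no response) for every row of ``terms``."""
    mc = normalize_model_class(model_class)
    groups = terms.attrs.get("groups") or plot.groups
    tab = _merge_terms(terms, plot)
    X = pd.DataFrame(index=tab.index)
    X["intercept"] = 1.0
    if response == "survival":
        X["inv_dbh"] = 1.0 / tab["dbh0"]
        X["dbh"] = tab["dbh0"]
        X["dbh2"] = tab["dbh0"] ** 2
    elif response == "growth":
        X["log_dbh"] = np.log(tab["dbh0"])
    else:
        raise ValueError(f"unknown response {response!r}")
    if mc in ("SIZE_DI", "SIZE_DI_HOI"):
        for c in di_column_names(groups):
            X[c] = tab[c]
    if mc == "SIZE_DI_HOI":
        for c in hoi_column_names(groups):
            X[c] = tab[c]
    bad = ~np.isfinite(X.to_numpy()).all(axis=1)
    if bad.any():
        raise ValueError("non-finite covariate for focal id(s) "
                         f"{tab.loc[bad, 'focal_id'].tolist()[:5]}")
    X.index = pd.Index(tab["focal_id"], name="focal_id")
    return X


def build_design(terms: pd.DataFrame, plot: CensusPlot, response: str,
                 model_class: str, min_increment: float = 0.0):
    """Design matrix and response vector for one model class.

    Survival keeps every focal (response: alive1).  Growth keeps focals alive
    at census 2 whose DBH increment exceeds ``min_increment`` (default 0,
    strictly — the log response requires positivity); response is
    ln(dbh1 - dbh0).
    """
    mc = normalize_model_class(model_class)
    tab = _merge_terms(terms, plot)
    if response == "growth":
        inc = tab["dbh1"] - tab["dbh0"]
        keep = (tab["alive1"] == 1) & (inc > min_increment)
        if not keep.any():
            raise FitError("growth model: no surviving focal with "
                           f"increment > {min_increment:g} cm")
        tab = tab[keep]
        y = pd.Series(np.log((tab["dbh1"] - tab["dbh0"]).to_numpy(float)),
                      index=pd.Index(tab["focal_id"], name="focal_id"),
                      name="log_growth")
        sub_terms = terms[terms["focal_id"].isin(tab["focal_id"])].copy()
        sub_terms.attrs.update(terms.attrs)
        X = build_covariates(sub_terms, plot, response, mc)
    elif response == "survival":
        y = pd.Series(tab["alive1"].to_numpy(int),
                      index=pd.Index(tab["focal_id"], name="focal_id"),
                      name="alive1")
        X = build_covariates(terms, plot, response, mc)
    else:
        raise ValueError(f"unknown response {response!r}")
    return X, y


def _kernel_meta(terms_or_X) -> dict:
    a = terms_or_X.attrs if hasattr(terms_or_X, "attrs") else {}
    return {k: a.get(k) for k in ("u", "v", "R")}


def fit_survival(X: pd.DataFrame, y: pd.Series, kernel: dict | None = None,
                 groups: list | None = None,
                 focal_group: str | None = None) -> FitResult:
    """Maximum-likelihood logistic fit of survival on the design matrix.

    Non-intercept columns are standardised internally for numerical
    stability (the kernel sums span orders of magnitude across the (u, v)
    grid); coefficients and standard errors are returned on the original
    scale — the MLE is invariant to the rescaling.
    """
    yv = y.to_numpy(float)
    if len(np.unique(yv)) < 2:
        raise FitError("survival response has a single outcome class; "
                       "the MLE direction is undefined")
    scale = X.std(axis=0).replace(0.0, 1.0)
    scale["intercept"] = 1.0
    Xs = X / scale
    try:
        res = sm.Logit(yv, Xs.to_numpy()).fit(
            method="newton", maxiter=MAX_ITER, tol=LOGLIK_RTOL, disp=0)
    except PerfectSeparationError as exc:
        raise FitError("perfect separation in the survival fit; consider a "
                       "regularised refit or pooling groups") from exc
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        grad = np.linalg.norm(res.model.score(res.params))
        raise FitError(f"logistic fit did not converge in {MAX_ITER} "
                       f"iterations (gradient norm {grad:.3g})")
    params = pd.Series(res.params, index=X.columns) / scale
    bse = pd.Series(res.bse, index=X.columns) / scale
    return FitResult(
        response="survival", model_class=_class_from_columns(X, "survival"),
        params=params, bse=bse, loglik=float(res.llf), k=X.shape[1],
        n=len(y), r2=float(res.prsquared), kernel=kernel or {},
        groups=groups or _groups_from_columns(X), focal_group=focal_group)


def fit_growth(X: pd.DataFrame, y: pd.Series, kernel: dict | None = None,
               groups: list | None = None,
               focal_group: str | None = None) -> FitResult:
    """OLS fit of log growth; loglik is the Gaussian profile likelihood."""
    if len(y) < X.shape[1] + 1:
        raise FitError(f"growth fit needs at least k+1 = {X.shape[1] + 1} "
                       f"rows, got {len(y)}")
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(Xv, mode="r")))
        bad = [c for c, r in zip(X.columns, rdiag)
               if r <= rdiag.max() * 1e-10]
        raise FitError(f"rank-deficient design; collinear column(s): {bad}")
    res = sm.OLS(y.to_numpy(float), Xv).fit()
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    return FitResult(
        response="growth", model_class=_class_from_columns(X, "growth"),
        params=params, bse=bse, loglik=float(res.llf), k=X.shape[1],
        n=len(y), r2=float(res.rsquared), kernel=kernel or {},
        groups=groups or _groups_from_columns(X), focal_group=focal_group)


def _class_from_columns(X: pd.DataFrame, response: str) -> str:
    has_di = any(c.startswith("di_") for c in X.columns)
    has_hoi = any(c.startswith("hoi_") for c in X.columns)
    return "SIZE_DI_HOI" if has_hoi else ("SIZE_DI" if has_di else "SIZE")


def _groups_from_columns(X: pd.DataFrame) -> list:
    return sorted(c[len("di_"):] for c in X.columns if c.startswith("di_"))


def fit_model(terms: pd.DataFrame, plot: CensusPlot, response: str,
              model_class: str, focal_group: str | None = None,
              min_increment: float = 0.0) -> FitResult:
    """Convenience wrapper: build the design from a term table and fit."""
    X, y = build_design(terms, plot, response, model_class, min_increment)
    groups = terms.attrs.get("groups") or plot.groups
    fn = fit_survival if response == "survival" else fit_growth
    return fn(X, y, kernel=_kernel_meta(terms), groups=list(groups),
              focal_group=focal_group or terms.attrs.get("focal_group"))


def linear_predictor(fit: FitResult, terms: pd.DataFrame,
                     plot: CensusPlot) -> pd.Series:
    """eta = X @ params for every row of ``terms``."""
    t_groups = terms.attrs.get("groups")
    if t_groups is not None and list(t_groups) != list(fit.groups):
        raise ValueError(f"grouping mismatch: fit has {fit.groups}, "
                         f"terms have {list(t_groups)}")
    X = build_covariates(terms, plot, fit.response, fit.model_class)
    missing = [c for c in fit.params.index if c not in X.columns]
    if missing:
        raise ValueError(f"terms lack required columns {missing}")
    eta = X[fit.params.index].to_numpy(float) @ fit.params.to_numpy(float)
    return pd.Series(eta, index=X.index, name="eta")


def predict(fit: FitResult, terms: pd.DataFrame, plot: CensusPlot) -> pd.Series:
    """Natural-scale prediction: survival probability or growth increment (cm)."""
    eta = linear_predictor(fit, terms, plot)
    if fit.response == "survival":
        from scipy.special import expit
        return pd.Series(expit(eta.to_numpy()), index=eta.index,
                         name="p_survive")
    return pd.Series(np.exp(eta.to_numpy()), index=eta.index,
                     name="growth_cm")
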