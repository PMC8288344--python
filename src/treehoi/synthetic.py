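"""Synthetic stem-mapped forests with known ground truth.

The generator emulates the study system the method targets: a rectangular
mapped plot holding one abundant group spread essentially everywhere
(Beech-like, homogeneous Poisson) and one rare, spatially aggregated group
(Spruce-like, Thomas cluster process), DBH log-normal with the 1-cm census
floor.  Fates are drawn from the survival and growth models themselves —
survival Bernoulli on the logistic linear predictor, growth multiplicative
log-normal with mean correction — so the generative family and the fitted
family coincide and parameter recovery is the definitive end-to-end test of
the term computation plus the fitting machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree
from scipy.special import expit

from .census import CensusPlot, GroupingScheme, assign_groups
from .evaluation import GridSpec, grid_search, information_criteria
from .interactions import KernelParams, terms_batch
from .models import (FitError, GrowthCoefficients, SurvivalCoefficients,
                     fit_model)

logger = logging.getLogger("treehoi")

MIN_SEPARATION_M = 1e-3   # 1 mm; the 1/d^v kernel needs distinct coordinates


@dataclass(frozen=True)
class GroupSpec:
    """One simulated population: abundance, spatial mode, DBH distribution."""

    name: str
    abundance: int
    spatial: str = "poisson"           # "poisson" | "thomas"
    n_parents: int = 10                # thomas: Poisson-parent count
    cluster_sd: float = 5.0            # thomas: offspring scatter, metres
    dbh_meanlog: float = np.log(5.0)   # log-normal DBH, cm
    dbh_sdlog: float = 0.5

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.spatial not in ("poisson", "thomas"):
            raise ValueError(f"unknown spatial mode {self.spatial!r}")


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to draw a two-census forest reproducibly."""

    bounds: tuple
    groups: tuple                       # GroupSpec, ...
    kernel: KernelParams
    survival: dict                      # group -> SurvivalCoefficients
    growth: dict                        # group -> GrowthCoefficients
    growth_noise_sd: float = 0.3        # log-scale
    allow_focal_initiator: bool = False
    seed: int = 0

    @property
    def group_names(self) -> list:
        return [g.name for g in self.groups]


def default_scenario(seed: int = 0) -> SimulationScenario:
    """The desk-scale analogue of the study regime.

    150 m x 150 m plot; group A 9000 stems, homogeneous Poisson (the
    abundant, widespread species; ~5000 of them focal-eligible inside the
    2R buffer); group B 340 stems in Thomas clusters (the rare, aggregated
    one); R = 10 m with kernel exponents (u, v) = (1.0, 0.8).  Direct effects are competitive (alpha < 0), higher-order effects
    facilitative (beta > 0) — the enemy-of-my-enemy regime.  Magnitudes
    follow a strong-effects rule: what identifies the coefficients and the
    kernel exponents is the between-focal *variation* each term contributes
    to the linear predictor (its mean is absorbed by the intercept), so each
    coefficient is sized to contribute roughly 0.3 linear-predictor units of
    standard deviation — comparable to the growth model's residual scale —
    for a typical realisation of this plot.
    """
    names = ("A", "B")
    alpha = {"A": -0.008, "B": -0.02}
    beta = {("A", "A"): 3e-5, ("A", "B"): 1e-4,
            ("B", "A"): 8e-5, ("B", "B"): 3e-4}
    surv = {n: SurvivalCoefficients(
        lambda_i=2.0 if n == "A" else 1.5,
        gamma1=-0.6, gamma2=0.02, gamma3=-2e-4,
        alpha=dict(alpha), beta=dict(beta)) for n in names}
    grow_alpha = {"A": -0.012, "B": -0.03}
    grow_beta = {("A", "A"): 5e-5, ("A", "B"): 2e-4,
                 ("B", "A"): 1.5e-4, ("B", "B"): 5e-4}
    grow = {n: GrowthCoefficients(
        g_pot=1.2 if n == "A" else 1.0, gamma=0.25,
        alpha=dict(grow_alpha), beta=dict(grow_beta)) for n in names}
    return SimulationScenario(
        bounds=(0.0, 150.0, 0.0, 150.0),
        groups=(GroupSpec(name="A", abundance=9000, spatial="poisson"),
                GroupSpec(name="B", abundance=340, spatial="thomas",
                          n_parents=34, cluster_sd=6.0)),
        kernel=KernelParams(u=1.0, v=0.8, R=10.0),
        survival=surv, growth=grow, growth_noise_sd=0.3, seed=seed)


def null_hoi_scenario(base: SimulationScenario) -> SimulationScenario:
    """Copy of ``base`` with every higher-order coefficient set to zero."""
    surv = {g: replace(c, beta={k: 0.0 for k in c.beta})
            for g, c in base.survival.items()}
    grow = {g: replace(c, beta={k: 0.0 for k in c.beta})
            for g, c in base.growth.items()}
    return replace(base, survival=surv, growth=grow)


# ---------------------------------------------------------------------------
# Point patterns


def _draw_positions(spec: GroupSpec, bounds, rng) -> np.ndarray:
    xmin, xmax, ymin, ymax = bounds
    if spec.spatial == "poisson":
        x = rng.uniform(xmin, xmax, spec.abundance)
        y = rng.uniform(ymin, ymax, spec.abundance)
        return np.column_stack([x, y])
    parents = np.column_stack([rng.uniform(xmin, xmax, spec.n_parents),
                               rng.uniform(ymin, ymax, spec.n_parents)])
    pts = np.empty((spec.abundance, 2))
    filled = 0
    while filled < spec.abundance:
        need = spec.abundance - filled
        centre = parents[rng.integers(0, spec.n_parents, need)]
        cand = centre + rng.normal(0, spec.cluster_sd, (need, 2))
        ok = ((cand[:, 0] >= xmin) & (cand[:, 0] <= xmax)
              & (cand[:, 1] >= ymin) & (cand[:, 1] <= ymax))
        n_ok = int(ok.sum())
        pts[filled:filled + n_ok] = cand[ok]
        filled += n_ok
    return pts


def _enforce_separation(xy: np.ndarray, bounds, rng,
                        max_rounds: int = 100) -> np.ndarray:
    xmin, xmax, ymin, ymax = bounds
    for _ in range(max_rounds):
        pairs = cKDTree(xy).query_pairs(r=MIN_SEPARATION_M,
                                        output_type="ndarray")
        if len(pairs) == 0:
            return xy
        move = np.unique(pairs[:, 1])
        xy[move] += rng.normal(0, 0.01, (len(move), 2))
        xy[move, 0] = np.clip(xy[move, 0], xmin, xmax)
        xy[move, 1] = np.clip(xy[move, 1], ymin, ymax)
    raise RuntimeError("could not separate stems by 1 mm after "
                       f"{max_rounds} jitter rounds")


def simulate_forest(scenario: SimulationScenario) -> CensusPlot:
    """Draw the census-1 stem map: positions, groups and DBH.

    Group counts match the requested abundances exactly; Thomas-mode groups
    are spatially aggregated.  Deterministic given the scenario seed.
    """
    root = np.random.SeedSequence(scenario.seed)
    rng_pos, rng_dbh, rng_sep = (np.random.default_rng(s)
                                 for s in root.spawn(3))
    frames = []
    offset = 0
    for spec in scenario.groups:
        xy = _draw_positions(spec, scenario.bounds, rng_pos)
        dbh = np.maximum(
            1.0, rng_dbh.lognormal(spec.dbh_meanlog, spec.dbh_sdlog,
                                   spec.abundance))
        frames.append(pd.DataFrame({
            "id": [f"t{offset + i:06d}" for i in range(spec.abundance)],
            "species": spec.name, "x": xy[:, 0], "y": xy[:, 1],
            "dbh0": dbh, "alive1": 1, "dbh1": np.nan}))
        offset += spec.abundance
    trees = pd.concat(frames, ignore_index=True)
    xy = _enforce_separation(trees[["x", "y"]].to_numpy(float),
                             scenario.bounds, rng_sep)
    trees[["x", "y"]] = xy
    plot = CensusPlot(trees=trees, bounds=scenario.bounds)
    return assign_groups(plot, GroupingScheme(mode="by_species"))


# ---------------------------------------------------------------------------
# Fates


def _eta_survival(c: SurvivalCoefficients, tab: pd.DataFrame,
                  groups) -> np.ndarray:
    dbh = tab["dbh0"].to_numpy(float)
    eta = (c.lambda_i + c.gamma1 / dbh + c.gamma2 * dbh
           + c.gamma3 * dbh ** 2)
    for j in groups:
        eta = eta + c.alpha[j] * tab[f"di_{j}"].to_numpy(float)
    for j in groups:
        for k in groups:
            eta = eta + c.beta[(j, k)] * tab[f"hoi_{j}_{k}"].to_numpy(float)
    return eta


def _log_growth(c: GrowthCoefficients, tab: pd.DataFrame,
                groups) -> np.ndarray:
    dbh = tab["dbh0"].to_numpy(float)
    lg = np.log(c.g_pot) + c.gamma * np.log(dbh)
    for j in groups:
        lg = lg + c.alpha[j] * tab[f"di_{j}"].to_numpy(float)
    for j in groups:
        for k in groups:
            lg = lg + c.beta[(j, k)] * tab[f"hoi_{j}_{k}"].to_numpy(float)
    return lg


def simulate_fates(plot: CensusPlot,
                   scenario: SimulationScenario) -> CensusPlot:
    """Draw census-2 fates for every stem, buffer-zone trees included.

    Survival is Bernoulli on the logistic linear predictor at the scenario's
    true kernel; survivors get dbh1 = dbh0 + growth * exp(N(0, sd) - sd^2/2),
    the mean-corrected log-normal, so expected natural-scale growth equals
    the model prediction.  Buffer trees need fates because they act as
    neighbours even though they are never focal.
    """
    root = np.random.SeedSequence((scenario.seed, 1))
    rng_surv, rng_grow = (np.random.default_rng(s) for s in root.spawn(2))
    groups = plot.groups
    terms = terms_batch(plot, scenario.kernel,
                        focal_ids=plot.trees["id"].tolist(),
                        allow_focal_initiator=scenario.allow_focal_initiator)
    tab = terms.merge(plot.trees, left_on="focal_id", right_on="id",
                      validate="one_to_one")
    alive = np.zeros(len(tab), dtype=int)
    dbh1 = np.full(len(tab), np.nan)
    sd = scenario.growth_noise_sd
    for g in groups:
        m = (tab["group"] == g).to_numpy()
        sub = tab[m]
        p = expit(_eta_survival(scenario.survival[g], sub, groups))
        a = rng_surv.binomial(1, p)
        growth = np.exp(_log_growth(scenario.growth[g], sub, groups))
        noise = np.exp(rng_grow.normal(0.0, sd, m.sum()) - sd ** 2 / 2)
        alive[m] = a
        d1 = sub["dbh0"].to_numpy(float) + growth * noise
        d1[a == 0] = np.nan
        dbh1[m] = d1
    trees = plot.trees.copy()
    order = tab.set_index("focal_id")
    trees["alive1"] = pd.Series(alive, index=tab["focal_id"]).reindex(
        trees["id"]).to_numpy()
    trees["dbh1"] = pd.Series(dbh1, index=tab["focal_id"]).reindex(
        trees["id"]).to_numpy()
    return CensusPlot(trees=trees, bounds=plot.bounds)


def simulate_census(scenario: SimulationScenario) -> CensusPlot:
    """Convenience: census-1 stem map plus simulated census-2 fates."""
    return simulate_fates(simulate_forest(scenario), scenario)


# ---------------------------------------------------------------------------
# Point-pattern diagnostics


def clark_evans_index(plot: CensusPlot, group: str | None = None) -> float:
    """Observed / expected mean nearest-neighbour distance (1 = Poisson).

    Values well below 1 indicate aggregation; above 1, regularity.  No edge
    correction — adequate for the generator's diagnostic use at desk scale.
    """
    t = plot.trees
    if group is not None:
        t = t[t["group"] == group]
    xy = t[["x", "y"]].to_numpy(float)
    if len(xy) < 2:
        raise ValueError("need at least two trees")
    d, _ = cKDTree(xy).query(xy, k=2)
    xmin, xmax, ymin, ymax = plot.bounds
    density = len(xy) / ((xmax - xmin) * (ymax - ymin))
    return float(d[:, 1].mean() / (0.5 / np.sqrt(density)))


def ripley_k(plot: CensusPlot, r: float, group: str | None = None) -> float:
    """Border-corrected Ripley's K(r); Poisson expectation is pi r^2."""
    t = plot.trees
    if group is not None:
        t = t[t["group"] == group]
    xy = t[["x", "y"]].to_numpy(float)
    xmin, xmax, ymin, ymax = plot.bounds
    density = len(xy) / ((xmax - xmin) * (ymax - ymin))
    interior = ((xy[:, 0] >= xmin + r) & (xy[:, 0] <= xmax - r)
                & (xy[:, 1] >= ymin + r) & (xy[:, 1] <= ymax - r))
    centres = xy[interior]
    if len(centres) == 0:
        raise ValueError("no interior centres at this r")
    counts = cKDTree(xy).query_ball_point(centres, r, return_length=True)
    return float((counts.mean() - 1) / density)   # -1: remove the centre


# ---------------------------------------------------------------------------
# Recovery and selection experiments


def _truth_map(scenario: SimulationScenario, response: str,
               focal_group: str) -> dict:
    groups = scenario.group_names
    if response == "survival":
        c = scenario.survival[focal_group]
        truth = {"intercept": c.lambda_i, "inv_dbh": c.gamma1,
                 "dbh": c.gamma2, "dbh2": c.gamma3}
    else:
        c = scenario.growth[focal_group]
        # mean-corrected log-normal noise shifts the log-scale intercept
        truth = {"intercept": np.log(c.g_pot) - scenario.growth_noise_sd ** 2 / 2,
                 "log_dbh": c.gamma}
    for j in groups:
        truth[f"di_{j}"] = c.alpha[j]
    for j in groups:
        for k in groups:
            truth[f"hoi_{j}_{k}"] = c.beta[(j, k)]
    return truth


def _replicate_seeds(seed: int, n: int) -> list:
    return [int(s % (2 ** 31)) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)]


def recovery_experiment(scenario: SimulationScenario, n_replicates: int = 20,
                        seed: int = 0, focal_group: str | None = None,
                        responses: tuple = ("survival", "growth"),
                        ci_level: float = 0.95) -> pd.DataFrame:
    """Simulate -> compute terms at the true kernel -> fit SIZE+DI+HOI, repeatedly.

    Returns one row per (response, coefficient): truth, mean estimate, bias,
    Monte-Carlo standard error of the mean, RMSE, and the fraction of
    ``ci_level`` Wald intervals covering truth.  Fit failures are counted in
    the ``n_fits`` column rather than aborting the experiment.
    """
    focal_group = focal_group or scenario.groups[0].name
    est: dict = {r: [] for r in responses}
    cover: dict = {r: [] for r in responses}
    for rep_seed in _replicate_seeds(seed, n_replicates):
        sc = replace(scenario, seed=rep_seed)
        plot = simulate_census(sc)
        terms = terms_batch(plot, sc.kernel, focal_group=focal_group,
                            allow_focal_initiator=sc.allow_focal_initiator)
        for response in responses:
            try:
                fit = fit_model(terms, plot, response, "SIZE_DI_HOI",
                                focal_group=focal_group)
            except FitError as exc:
                logger.warning("replicate fit failed (%s): %s", response, exc)
                continue
            est[response].append(fit.params)
            ci = fit.conf_int(ci_level)
            truth = _truth_map(sc, response, focal_group)
            cover[response].append(pd.Series(
                {name: ci.at[name, "lower"] <= truth[name] <= ci.at[name, "upper"]
                 for name in fit.params.index}))
    rows = []
    for response in responses:
        if not est[response]:
            continue
        E = pd.DataFrame(est[response])
        C = pd.DataFrame(cover[response])
        truth = _truth_map(scenario, response, focal_group)
        for name in E.columns:
            e = E[name].to_numpy(float)
            t = truth[name]
            rows.append({
                "response": response, "coefficient": name, "truth": t,
                "mean_estimate": e.mean(), "bias": e.mean() - t,
                "mc_se": e.std(ddof=1) / np.sqrt(len(e)),
                "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
                "coverage": float(C[name].mean()), "n_fits": len(e)})
    return pd.DataFrame(rows)


def model_selection_experiment(scenario: SimulationScenario,
                               n_replicates: int = 20, seed: int = 0,
                               response: str = "growth",
                               focal_group: str | None = None) -> pd.DataFrame:
    """Which model class wins AIC at the true kernel, per replicate."""
    focal_group = focal_group or scenario.groups[0].name
    rows = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        sc = replace(scenario, seed=rep_seed)
        plot = simulate_census(sc)
        terms = terms_batch(plot, sc.kernel, focal_group=focal_group,
                            allow_focal_initiator=sc.allow_focal_initiator)
        aics = {}
        for mc in ("SIZE", "SIZE_DI", "SIZE_DI_HOI"):
            fit = fit_model(terms, plot, response, mc,
                            focal_group=focal_group)
            aics[mc] = information_criteria(fit)[0]
        winner = min(aics, key=aics.get)
        rows.append({"seed": rep_seed, "winner": winner, **aics})
    return pd.DataFrame(rows)


def grid_recovery_experiment(scenario: SimulationScenario,
                             u_values, v_values,
                             n_replicates: int = 10, seed: int = 0,
                             response: str = "growth",
                             focal_group: str | None = None) -> pd.DataFrame:
    """Recover the kernel exponents by grid argmax, per replicate."""
    focal_group = focal_group or scenario.groups[0].name
    grid = GridSpec(radii=(scenario.kernel.R,),
                    u_values=tuple(u_values), v_values=tuple(v_values))
    rows = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        sc = replace(scenario, seed=rep_seed)
        plot = simulate_census(sc)
        res = grid_search(plot, None, response, "SIZE_DI_HOI", grid,
                          focal_group=focal_group)[scenario.kernel.R]
        rows.append({"seed": rep_seed, "u_hat": res.u_opt,
                     "v_hat": res.v_opt,
                     "u_err": abs(res.u_opt - scenario.kernel.u),
                     "v_err": abs(res.v_opt - scenario.kernel.v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario files


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _coeff_to_dict(c) -> dict:
    d = {k: float(v) for k, v in vars(c).items()
         if k not in ("alpha", "beta")}
    d["alpha"] = {k: float(v) for k, v in c.alpha.items()}
    d["beta"] = {f"{j},{k}": float(v) for (j, k), v in c.beta.items()}
    return d


def save_scenario(scenario: SimulationScenario, path) -> None:
    doc = {
        "bounds": [float(b) for b in scenario.bounds],
        "seed": int(scenario.seed),
        "growth_noise_sd": float(scenario.growth_noise_sd),
        "allow_focal_initiator": bool(scenario.allow_focal_initiator),
        "kernel": {"u": float(scenario.kernel.u), "v": float(scenario.kernel.v),
                   "R": float(scenario.kernel.R)},
        "groups": [{k: _plain(v) for k, v in vars(g).items()}
                   for g in scenario.groups],
        "survival": {g: _coeff_to_dict(c) for g, c in scenario.survival.items()},
        "growth": {g: _coeff_to_dict(c) for g, c in scenario.growth.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def beta_keys(d):
        return {tuple(k.split(",")): float(v) for k, v in d.items()}

    surv = {g: SurvivalCoefficients(
                lambda_i=c["lambda_i"], gamma1=c["gamma1"],
                gamma2=c["gamma2"], gamma3=c["gamma3"],
                alpha={k: float(v) for k, v in c["alpha"].items()},
                beta=beta_keys(c["beta"]))
            for g, c in doc["survival"].items()}
    grow = {g: GrowthCoefficients(
                g_pot=c["g_pot"], gamma=c["gamma"],
                alpha={k: float(v) for k, v in c["alpha"].items()},
                beta=beta_keys(c["beta"]))
            for g, c in doc["growth"].items()}
    return SimulationScenario(
        bounds=tuple(doc["bounds"]),
        groups=tuple(GroupSpec(**g) for g in doc["groups"]),
        kernel=KernelParams(**doc["kernel"]),
        survival=surv, growth=grow,
        growth_noise_sd=doc.get("growth_noise_sd", 0.3),
        allow_focal_initiator=doc.get("allow_focal_initiator", False),
        seed=doc.get("seed", 0))
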