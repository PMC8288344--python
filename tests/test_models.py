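"""Design construction, logistic/OLS fitting, prediction."""

import numpy as np
import pandas as pd
import pytest

import treehoi as th
from conftest import make_plot


def _attach(terms, groups):
    terms.attrs["groups"] = groups
    return terms


class TestBuildDesign:
    def test_parameter_counts_two_groups(self, sim_plot, sim_terms):
        # survival: 4 size params + G + G^2; growth: 2 + G + G^2
        Xs, _ = th.build_design(sim_terms, sim_plot, "survival", "SIZE_DI_HOI")
        assert Xs.shape[1] == 10
        Xg, _ = th.build_design(sim_terms, sim_plot, "growth", "SIZE_DI_HOI")
        assert Xg.shape[1] == 8
        for mc, ks, kg in [("SIZE", 4, 2), ("SIZE_DI", 6, 4)]:
            X, _ = th.build_design(sim_terms, sim_plot, "survival", mc)
            assert X.shape[1] == ks
            X, _ = th.build_design(sim_terms, sim_plot, "growth", mc)
            assert X.shape[1] == kg

    def test_single_group_counts(self):
        plot = make_plot([("f", "A", 10, 10, 5), ("n", "A", 12, 10, 3)],
                         bounds=(0, 20, 0, 20))
        trees = plot.trees.copy()
        trees.loc[:, "alive1"] = [1, 0]
        trees.loc[0, "dbh1"] = 6.0
        plot = th.CensusPlot(trees=trees, bounds=plot.bounds)
        plot = th.assign_groups(plot, th.GroupingScheme())
        terms = th.terms_batch(plot, th.KernelParams(1, 1, 4),
                               focal_ids=["f", "n"])
        X, y = th.build_design(terms, plot, "survival", "SIZE_DI_HOI")
        assert X.shape[1] == 6          # 4 + 1 + 1
        assert list(y) == [1, 0]

    def test_growth_filter_requires_positive_increment(self, sim_plot,
                                                       sim_terms):
        _, y = th.build_design(sim_terms, sim_plot, "growth", "SIZE")
        merged = sim_terms.merge(sim_plot.trees, left_on="focal_id",
                                 right_on="id")
        n_pos = ((merged["alive1"] == 1)
                 & (merged["dbh1"] - merged["dbh0"] > 0)).sum()
        assert len(y) == n_pos
        assert np.isfinite(y).all()


class TestFitSurvival:
    def test_all_alive_rejected(self, sim_plot, sim_terms):
        X, y = th.build_design(sim_terms, sim_plot, "survival", "SIZE")
        with pytest.raises(th.FitError, match="single outcome"):
            th.fit_survival(X, y * 0 + 1)

    def test_recovers_truth_within_3se(self, sim_plot, sim_scenario,
                                       sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "survival", "SIZE_DI_HOI",
                           focal_group="A")
        truth = sim_scenario.survival["A"]
        named = {"di_A": truth.alpha["A"], "di_B": truth.alpha["B"],
                 **{f"hoi_{j}_{k}": truth.beta[(j, k)]
                    for j in "AB" for k in "AB"}}
        for name, t in named.items():
            z = (fit.params[name] - t) / fit.bse[name]
            assert abs(z) < 3, f"{name}: z = {z:.2f}"

    def test_zero_coefficients_predict_half(self, sim_plot, sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "survival", "SIZE_DI_HOI",
                           focal_group="A")
        fit.params[:] = 0.0
        p = th.predict(fit, sim_terms, sim_plot)
        assert np.allclose(p, 0.5)

    def test_probability_bounds(self, sim_plot, sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "survival", "SIZE_DI_HOI")
        p = th.predict(fit, sim_terms, sim_plot)
        assert ((p >= 0) & (p <= 1)).all()


class TestFitGrowth:
    def test_recovers_truth_within_3se(self, sim_plot, sim_scenario,
                                       sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "growth", "SIZE_DI_HOI",
                           focal_group="A")
        truth = sim_scenario.growth["A"]
        named = {"log_dbh": truth.gamma,
                 "di_A": truth.alpha["A"], "di_B": truth.alpha["B"],
                 **{f"hoi_{j}_{k}": truth.beta[(j, k)]
                    for j in "AB" for k in "AB"}}
        for name, t in named.items():
            z = (fit.params[name] - t) / fit.bse[name]
            assert abs(z) < 3, f"{name}: z = {z:.2f}"

    def test_gpot_is_prediction_for_unit_dbh_no_neighbours(self):
        params = pd.Series({"intercept": np.log(1.7), "log_dbh": 0.4,
                            "di_A": -0.1, "hoi_A_A": 0.01})
        fit = th.FitResult(response="growth", model_class="SIZE_DI_HOI",
                           params=params, bse=params * np.nan, loglik=0.0,
                           k=4, n=10, r2=0.5, kernel={}, groups=["A"])
        terms = _attach(pd.DataFrame({"focal_id": ["f"], "di_A": [0.0],
                                      "hoi_A_A": [0.0]}), ["A"])
        plot = make_plot([("f", "A", 10, 10, 1.0)], bounds=(0, 20, 0, 20))
        pred = th.predict(fit, terms, plot)
        assert pred.iloc[0] == pytest.approx(1.7)   # DBH^gamma = 1, e^0 = 1

    def test_hand_computed_growth_prediction(self):
        # Growth = G_pot * DBH^gamma * exp(DI) * exp(HOI)
        g_pot, gamma, a, b = 1.3, 0.5, -0.2, 0.05
        params = pd.Series({"intercept": np.log(g_pot), "log_dbh": gamma,
                            "di_A": a, "hoi_A_A": b})
        fit = th.FitResult(response="growth", model_class="SIZE_DI_HOI",
                           params=params, bse=params * np.nan, loglik=0.0,
                           k=4, n=10, r2=0.5, kernel={}, groups=["A"])
        terms = _attach(pd.DataFrame({"focal_id": ["f"], "di_A": [2.5],
                                      "hoi_A_A": [4.0]}), ["A"])
        plot = make_plot([("f", "A", 10, 10, 9.0)], bounds=(0, 20, 0, 20))
        expected = g_pot * 9.0 ** gamma * np.exp(a * 2.5) * np.exp(b * 4.0)
        assert th.predict(fit, terms, plot).iloc[0] == pytest.approx(expected)

    def test_scale_equivariance(self, sim_plot, sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "growth", "SIZE_DI",
                           focal_group="A")
        doubled = sim_terms.copy()
        doubled.attrs.update(sim_terms.attrs)
        for c in doubled.columns:
            if c.startswith("di_"):
                doubled[c] = doubled[c] * 2
        fit2 = th.fit_model(doubled, sim_plot, "growth", "SIZE_DI",
                            focal_group="A")
        for c in ("di_A", "di_B"):
            assert fit2.params[c] == pytest.approx(fit.params[c] / 2)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"intercept": 1.0, "log_dbh": rng.normal(size=30)})
        X["di_A"] = 2 * X["log_dbh"]
        y = pd.Series(rng.normal(size=30))
        with pytest.raises(th.FitError, match="di_A|log_dbh"):
            th.fit_growth(X, y)

    def test_too_few_rows(self):
        X = pd.DataFrame({"intercept": [1.0, 1.0], "log_dbh": [0.1, 0.2]})
        with pytest.raises(th.FitError, match="rows"):
            th.fit_growth(X, pd.Series([0.5, 0.6]))


class TestNesting:
    @pytest.mark.parametrize("response", ["survival", "growth"])
    def test_loglik_monotone_in_class(self, sim_plot, sim_terms, response):
        lls = [th.fit_model(sim_terms, sim_plot, response, mc,
                            focal_group="A").loglik
               for mc in ("SIZE", "SIZE_DI", "SIZE_DI_HOI")]
        assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6

    def test_grouping_mismatch_rejected(self, sim_plot, sim_terms):
        fit = th.fit_model(sim_terms, sim_plot, "growth", "SIZE_DI_HOI")
        bad = sim_terms.copy()
        bad.attrs.update(sim_terms.attrs)
        bad.attrs["groups"] = ["A", "C"]
        with pytest.raises(ValueError, match="[Gg]rouping"):
            th.predict(fit, bad, sim_plot)
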