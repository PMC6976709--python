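"""Driver-attribution tests: ANOVA/Tukey, random-forest fits and importance,
accumulated local effects against closed-form and numerical oracles, and
predictor ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from planktransect.model import (
    TaxonDriverModel,
    ablate_predictor,
    compare_water_masses,
    compute_ale,
    fit_rf,
    importance_ranking,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestCompareWaterMasses:
    def test_null_case_not_significant(self, rng):
        conc = pd.DataFrame({"taxon": rng.normal(5, 1, 300)})
        labels = np.repeat(["FC", "IF", "ED"], 100)
        anova, tukey = compare_water_masses(conc, labels)
        assert anova.loc["taxon", "p"] > 0.05
        assert tukey.empty

    def test_planted_eddy_enrichment_detected(self, rng):
        labels = np.repeat(["FC", "IF", "ED"], 100)
        y = rng.normal(2, 0.5, 300)
        y[labels == "ED"] += 3.0
        anova, tukey = compare_water_masses(pd.DataFrame({"taxon": y}), labels)
        assert anova.loc["taxon", "p"] < 0.05
        pair = tukey[
            (tukey.taxon == "taxon")
            & (tukey[["group1", "group2"]].apply(set, axis=1) == {"ED", "FC"})
        ]
        assert pair.reject.iloc[0]

    def test_two_groups_reduces_to_t_test(self, rng):
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)])
        labels = np.repeat(["FC", "ED"], 40)
        anova, _ = compare_water_masses(pd.DataFrame({"x": y}), labels)
        t, p = stats.ttest_ind(y[:40], y[40:])
        assert anova.loc["x", "F"] == pytest.approx(t**2, rel=1e-10)
        assert anova.loc["x", "p"] == pytest.approx(p, rel=1e-10)

    def test_tukey_matches_studentized_range_brute_force(self, rng):
        # <= 30 observations: recompute Tukey-Kramer p-values directly
        y = np.concatenate([
            rng.normal(0, 1, 10), rng.normal(1.5, 1, 10), rng.normal(3, 1, 10)
        ])
        labels = np.repeat(["a", "b", "c"], 10)
        _, tukey = compare_water_masses(pd.DataFrame({"x": y}), labels)
        k, n = 3, 30
        groups = [y[labels == g] for g in ("a", "b", "c")]
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
        for _, row in tukey.iterrows():
            gi = y[labels == row.group1]
            gj = y[labels == row.group2]
            q = abs(gi.mean() - gj.mean()) / np.sqrt(mse / 2 * (1 / len(gi) + 1 / len(gj)))
            p_brute = stats.studentized_range.sf(q, k, n - k)
            assert row.p_adj == pytest.approx(p_brute, abs=1e-3)


class TestFitRF:
    def test_pure_noise_has_low_variance_explained(self, rng):
        tab = pd.DataFrame(rng.normal(0, 1, (400, 4)), columns=list("abcd"))
        tab["y"] = rng.normal(0, 1, 400)
        fit = fit_rf(tab, "y", n_trees=200, mtry=2, seed=0)
        assert fit.variance_explained <= 0.1

    def test_deterministic_response_ranks_its_predictor_first(self, rng):
        tab = pd.DataFrame(rng.normal(0, 1, (400, 4)), columns=list("abcd"))
        tab["y"] = np.sin(3 * tab["b"])
        fit = fit_rf(tab, "y", n_trees=200, mtry=2, seed=0)
        assert fit.variance_explained > 0.8
        assert fit.importance["node_purity"].idxmax() == "b"
        assert fit.importance["mse_increase"].idxmax() == "b"

    def test_mtry_exceeding_predictors_rejected(self, rng):
        tab = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        tab["y"] = tab["a"]
        with pytest.raises(ValueError, match="mtry"):
            fit_rf(tab, "y", mtry=14)

    def test_row_duplication_stable_top_predictors(self, rng):
        tab = pd.DataFrame(rng.normal(0, 1, (250, 4)), columns=list("abcd"))
        tab["y"] = 2 * tab["a"] + tab["c"] + rng.normal(0, 0.2, 250)
        top = set(importance_ranking(fit_rf(tab, "y", n_trees=200, mtry=2, seed=0), top=2).index)
        doubled = pd.concat([tab, tab], ignore_index=True)
        top2 = set(importance_ranking(fit_rf(doubled, "y", n_trees=200, mtry=2, seed=0), top=2).index)
        assert top == top2 == {"a", "c"}

    def test_categorical_predictor_importance_is_aggregated(self, rng):
        tab = pd.DataFrame({
            "water_mass": rng.choice(["FC", "IF", "ED"], 300),
            "x": rng.normal(0, 1, 300),
        })
        tab["y"] = tab.water_mass.map({"FC": 0.0, "IF": 1.0, "ED": 2.0}) + rng.normal(0, 0.1, 300)
        fit = fit_rf(tab, "y", n_trees=200, mtry=2, seed=0)
        assert set(fit.importance.index) == {"water_mass", "x"}
        assert fit.importance["mse_increase"].idxmax() == "water_mass"

    def test_importance_ranking_complete_and_ordered(self, rng):
        tab = pd.DataFrame(rng.normal(0, 1, (300, 3)), columns=["strong", "weak", "null"])
        tab["y"] = 3 * tab["strong"] + 0.4 * tab["weak"] + rng.normal(0, 0.3, 300)
        ranking = importance_ranking(fit_rf(tab, "y", n_trees=200, mtry=2, seed=0))
        assert list(ranking.index) == ["strong", "weak", "null"]
        assert {"node_purity", "mse_increase"} <= set(ranking.columns)


class TestALE:
    def test_linear_function_closed_form(self, rng):
        tab = pd.DataFrame({"x1": rng.uniform(0, 1, 2000), "x2": rng.normal(0, 1, 2000)})
        curve = compute_ale(lambda df: 3.0 * df["x1"].to_numpy(), tab, "x1")
        expected = 3.0 * curve.grid - 1.5  # centered linear effect
        bin_width = np.diff(curve.grid).max()
        assert np.abs(curve.effect - expected).max() < 3 * bin_width

    def test_constant_function_zero_everywhere(self, rng):
        tab = pd.DataFrame({"x1": rng.uniform(0, 1, 500), "x2": rng.normal(0, 1, 500)})
        curve = compute_ale(lambda df: np.full(len(df), 7.0), tab, "x1")
        np.testing.assert_allclose(curve.effect, 0.0, atol=1e-12)

    def test_centering_continuous(self, rng):
        tab = pd.DataFrame({"x1": rng.uniform(0, 1, 1000), "x2": rng.normal(0, 1, 1000)})
        curve = compute_ale(lambda df: np.exp(df["x1"].to_numpy()), tab, "x1")
        mid = 0.5 * (curve.effect[:-1] + curve.effect[1:])
        assert abs(np.average(mid, weights=curve.counts)) < 1e-8

    def test_centering_categorical(self, rng):
        tab = pd.DataFrame({
            "wm": rng.choice(["FC", "IF", "ED"], 600),
            "x": rng.normal(0, 1, 600),
        })
        effect_map = {"FC": -1.0, "IF": 0.5, "ED": 2.0}
        curve = compute_ale(
            lambda df: df["wm"].map(effect_map).to_numpy(float), tab, "wm"
        )
        assert curve.categorical
        assert abs(np.average(curve.effect, weights=curve.counts)) < 1e-8
        # pairwise differences of the planted effects are recovered
        lut = dict(zip(curve.grid, curve.effect))
        assert lut["ED"] - lut["FC"] == pytest.approx(3.0, abs=1e-8)

    def test_correlated_additive_not_inflated(self, rng):
        # f = x1 + x2 with strongly correlated predictors: ALE slope of each
        # must stay ~1 (a partial-dependence-style average would inflate it)
        z = rng.normal(0, 1, 4000)
        tab = pd.DataFrame({
            "x1": z + 0.3 * rng.normal(0, 1, 4000),
            "x2": z + 0.3 * rng.normal(0, 1, 4000),
        })
        f = lambda df: df["x1"].to_numpy() + df["x2"].to_numpy()
        for p in ("x1", "x2"):
            curve = compute_ale(f, tab, p)
            slope = np.polyfit(curve.grid, curve.effect, 1)[0]
            assert slope == pytest.approx(1.0, abs=0.05)

    def test_additive_components_recovered_within_bin_resolution(self, rng):
        # numerical oracle: for an additive f the ALE of x1 is its component
        # centered by the data-weighted mean
        x1 = rng.uniform(0, 1, 3000)
        tab = pd.DataFrame({"x1": x1, "x2": x1 + 0.2 * rng.normal(0, 1, 3000)})
        comp = lambda x: x**2
        f = lambda df: comp(df["x1"].to_numpy()) + 0.5 * df["x2"].to_numpy()
        curve = compute_ale(f, tab, "x1", n_bins=25)
        oracle = comp(curve.grid) - np.mean(comp(x1))
        assert np.abs(curve.effect - oracle).max() < 0.05


@pytest.fixture(scope="module")
def driver_table():
    rng = np.random.default_rng(7)
    n = 500
    tab = pd.DataFrame({
        "informative": rng.uniform(0, 1, n),
        "null1": rng.normal(0, 1, n),
        "null2": rng.normal(0, 1, n),
    })
    tab["y"] = np.sin(6 * tab["informative"])
    return tab


class TestAblation:
    def test_ablating_null_predictor_changes_little(self, driver_table):
        res = ablate_predictor(driver_table, "y", "null1", n_trees=200, mtry=2, seed=0)
        assert abs(res["delta"]) < 0.01

    def test_ablating_sole_informative_predictor_collapses_fit(self, driver_table):
        res = ablate_predictor(driver_table, "y", "informative", n_trees=200, mtry=2, seed=0)
        assert res["delta"] > 0.5


class TestDriverModelFacade:
    def test_fit_summary_and_results_roundtrip(self, rng):
        tab = pd.DataFrame({
            "oithona": rng.lognormal(1, 0.5, 300),
            "current_speed": rng.uniform(0, 1, 300),
            "water_mass": rng.choice(["FC", "IF", "ED"], 300),
        })
        tab["larval_fish"] = (
            0.5 * np.log1p(tab["oithona"]) - tab["current_speed"]
            + rng.normal(0, 0.1, 300)
        )
        model = TaxonDriverModel(tab, response="larval_fish", n_trees=150, mtry=2)
        res = model.fit(seed=0)
        assert res.variance_explained > 0.5
        text = res.summary(top=3)
        assert "larval_fish" in text and "OOB variance explained" in text
        imp = res.importance(top=2)
        assert len(imp) == 2
        curve = res.ale("current_speed", n_bins=10)
        assert curve.effect.shape == curve.grid.shape
        preds = res.predict()
        assert np.corrcoef(preds, tab["larval_fish"])[0, 1] > 0.8
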