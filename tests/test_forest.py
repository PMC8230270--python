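"""RMSE/R-squared oracles, CV mechanics, permutation importance and selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from scfaforest.forest import (
    MicrobiotaForestModel,
    RFRConfig,
    evaluate_model_tiers,
    permutation_importance,
    r_squared,
    rmse,
    run_cv_rfr,
    run_group_analyses,
    select_predictive_species,
    train_size,
)

FAST = dict(n_runs=3, n_trees=30)


class TestErrorFormulas:
    def test_rmse_examples(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert rmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(np.sqrt(2 / 3))

    def test_r_squared_examples(self):
        y = [1.0, 2.0, 3.0]
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared([2.0, 2.0, 2.0], y) == pytest.approx(0.0)
        assert r_squared([1.0, 2.0, 2.0], y) == pytest.approx(0.5)

    def test_rmse_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert rmse(3.5 * x, 3.5 * y) == pytest.approx(3.5 * rmse(x, y))

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(2, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            direct_rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / n)
            ybar = sum(y) / n
            direct_r2 = 1 - sum((b - a) ** 2 for a, b in zip(x, y)) / sum(
                (b - ybar) ** 2 for b in y
            )
            assert rmse(x, y) == pytest.approx(direct_rmse, abs=1e-12)
            assert r_squared(x, y) == pytest.approx(direct_r2, abs=1e-12)

    def test_algebraic_consistency(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        sst = ((y - y.mean()) ** 2).sum()
        assert r_squared(x, y) == pytest.approx(1 - rmse(x, y) ** 2 * 15 / sst)

    def test_constant_actual_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(r_squared([1.0, 2.0], [3.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestSplitArithmetic:
    @pytest.mark.parametrize("n, expected", [(72, 54), (36, 27), (35, 26), (33, 25)])
    def test_train_size_rounds_to_nearest(self, n, expected):
        assert train_size(n, 0.75) == expected


@pytest.fixture(scope="module")
def noise_problem():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(40, 10)),
                     columns=[f"f{j}" for j in range(10)],
                     index=[f"S{i}" for i in range(40)])
    y = rng.normal(size=40)
    return X, y


class TestRunCV:
    def test_split_sizes_and_partition(self, noise_problem):
        X, y = noise_problem
        runs = run_cv_rfr(X, y, RFRConfig(seed=1, **FAST))
        for r in runs:
            assert len(r.train_ids) == 30 and len(r.test_ids) == 10
            assert set(r.train_ids) | set(r.test_ids) == set(X.index)
            assert set(r.train_ids) & set(r.test_ids) == set()
            assert np.isfinite(r.predicted).all()

    def test_seeded_determinism(self, noise_problem):
        X, y = noise_problem
        a = run_cv_rfr(X, y, RFRConfig(seed=9, **FAST))
        b = run_cv_rfr(X, y, RFRConfig(seed=9, **FAST))
        for ra, rb in zip(a, b):
            assert ra.test_ids == rb.test_ids
            np.testing.assert_array_equal(ra.predicted, rb.predicted)
            pd.testing.assert_series_equal(ra.importance, rb.importance)

    def test_constant_outcome_rejected(self, noise_problem):
        X, _ = noise_problem
        with pytest.raises(ValueError, match="constant outcome"):
            run_cv_rfr(X, np.ones(len(X)), RFRConfig(**FAST))

    def test_tiny_test_set_rejected(self, noise_problem):
        X, y = noise_problem
        with pytest.raises(ValueError, match="test samples"):
            run_cv_rfr(X.iloc[:9], y[:9], RFRConfig(train_fraction=0.9, **FAST))

    def test_pure_noise_r2_near_zero(self):
        """With y independent of X, mean test R-squared stays at chance level."""
        from scfaforest.forest import r_squared as r2

        means = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(40, 15)))
            X.index = [f"S{i}" for i in range(40)]
            y = rng.normal(size=40)
            runs = run_cv_rfr(X, y, RFRConfig(n_runs=10, n_trees=100, seed=seed))
            means.append(np.mean([r2(r.predicted, r.actual) for r in runs]))
        assert np.mean(means) <= 0.05


class TestPermutationImportance:
    def fit_forest(self, X, y, **kw):
        return RandomForestRegressor(n_estimators=100, random_state=0, **kw).fit(X, y)

    def test_constant_feature_importance_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"signal": rng.normal(size=60), "dead": np.zeros(60)})
        y = X["signal"].to_numpy() * 2
        model = self.fit_forest(X, y)
        imp = permutation_importance(model, X, y, seed=1)
        assert imp["dead"] == 0.0

    def test_deterministic_feature_dominates(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.uniform(-2, 2, size=200)})
        y = np.sin(X["x"].to_numpy()) * 5
        model = self.fit_forest(X, y)
        imp = permutation_importance(model, X, y, seed=1)
        assert imp["x"] > 50

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        model = self.fit_forest(X, y)
        a = permutation_importance(model, X, y, seed=7, n_repeats=3)
        b = permutation_importance(model, X, y, seed=7, n_repeats=3)
        pd.testing.assert_series_equal(a, b)

    def test_zero_baseline_mse_flagged(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = np.zeros(4)

        class Perfect:
            def predict(self, X):
                return np.zeros(len(X))

        with pytest.warns(UserWarning, match="zero baseline"):
            imp = permutation_importance(Perfect(), X, y, seed=0)
        assert np.isnan(imp["x"])


class TestSelection:
    def grid(self, means: dict):
        rows = [pd.Series(means), pd.Series(means)]
        runs = pd.DataFrame(rows).reset_index(drop=True)
        from scfaforest.forest import ImportanceMatrix

        return ImportanceMatrix(outcome="acetate", group="total", grid=runs)

    def test_strict_threshold(self):
        imp = self.grid({"A": 5.1, "B": 1.9, "C": 2.0})
        sel = select_predictive_species(imp, threshold=2.0)
        assert sel.selected == ["A"]

    def test_all_negative_empty(self):
        imp = self.grid({"A": -1.0, "B": -0.2})
        assert select_predictive_species(imp, threshold=2.0).selected == []

    def test_species_subset_excludes_confounders(self):
        imp = self.grid({"age": 9.0, "A": 3.0})
        sel = select_predictive_species(imp, threshold=2.0, species=["A"])
        assert sel.selected == ["A"]

    def test_frequency_mode(self):
        from scfaforest.forest import ImportanceMatrix

        grid = pd.DataFrame({"A": [3.0, 3.0, 0.0], "B": [9.0, 0.0, 0.0]})
        imp = ImportanceMatrix(outcome="x", group="total", grid=grid)
        sel = select_predictive_species(imp, threshold=2.0, mode="frequency")
        assert sel.selected == ["A"]


class TestTierEvaluation:
    def test_empty_selection_falls_back_to_baseline(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(24)]
        conf = pd.DataFrame(rng.normal(size=(24, 2)), columns=["age", "bmi"], index=idx)
        species = pd.DataFrame(rng.normal(size=(24, 3)) ** 2,
                               columns=["s1", "s2", "s3"], index=idx)
        y = conf["age"] * 2 + rng.normal(size=24)
        cfg = RFRConfig(seed=2, importance_threshold=1e9, **FAST)
        with pytest.warns(UserWarning, match="empty selection"):
            ev = evaluate_model_tiers(species, conf, y, cfg)
        assert ev.empty_selection
        base, _, final = ev.performances
        assert final.rmse_mean == base.rmse_mean

    def test_rmse_percent_arithmetic(self):
        rng = np.random.default_rng(1)
        idx = [f"S{i}" for i in range(24)]
        conf = pd.DataFrame(rng.normal(size=(24, 2)), columns=["a", "b"], index=idx)
        species = pd.DataFrame(rng.normal(size=(24, 2)) ** 2, columns=["s1", "s2"],
                               index=idx)
        y = pd.Series(rng.uniform(50, 150, size=24), index=idx)
        ev = evaluate_model_tiers(species, conf, y, RFRConfig(seed=3, **FAST))
        for p in ev.performances:
            assert p.rmse_percent == pytest.approx(100 * p.rmse_mean / y.mean())


class TestModelObject:
    def test_summary_mentions_key_facts(self, small_cohort):
        from scfaforest.tables import filter_species_for_rfr

        table, metadata = small_cohort
        filt = filter_species_for_rfr(table, metadata).table
        res = MicrobiotaForestModel.from_tables(
            filt, metadata, "acetate", config=RFRConfig(seed=0, **FAST)
        ).fit()
        text = res.summary()
        assert "acetate" in text and "baseline" not in text.split("\n")[0]
        assert res.performance.shape[0] == 3
        assert list(res.performance["tier"]) == ["baseline", "full", "final"]

    def test_identical_groups_identical_selections(self, small_cohort):
        """When omnivore data duplicates vegan data, per-group fits with one
        seed coincide."""
        table, metadata = small_cohort
        n = 12
        counts = table.counts.copy()
        counts.iloc[n:] = counts.iloc[:n].to_numpy()
        md = metadata.copy()
        cols = [c for c in md.columns if c != "diet_group"]
        md.loc[md.index[n:], cols] = md.iloc[:n][cols].to_numpy()
        from scfaforest.tables import AbundanceTable

        mirrored = AbundanceTable(counts=counts, lineage=table.lineage)
        cfg = RFRConfig(seed=4, **FAST)
        res_v = MicrobiotaForestModel.from_tables(mirrored, md, "butyrate",
                                                  group="vegan", config=cfg).fit()
        res_o = MicrobiotaForestModel.from_tables(mirrored, md, "butyrate",
                                                  group="omnivore", config=cfg).fit()
        assert res_v.selected_species == res_o.selected_species
        pd.testing.assert_frame_equal(
            res_v.performance.drop(columns="group"),
            res_o.performance.drop(columns="group"),
        )


class TestGroupAnalyses:
    def test_performance_cardinality(self, small_cohort):
        """Three groups x six outcomes x three tiers yields 54 performance rows."""
        from scfaforest.tables import filter_species_for_rfr

        table, metadata = small_cohort
        filt = filter_species_for_rfr(table, metadata).table
        analyses = run_group_analyses(
            filt, metadata, config=RFRConfig(seed=0, n_runs=2, n_trees=15)
        )
        assert analyses.performance.shape[0] == 54
        assert set(analyses.performance["tier"]) == {"baseline", "full", "final"}
        assert len(analyses.selections) == 18
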