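import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

import rqa_motion as rm
from rqa_motion.models import BaggedForest


def make_table(counts, n_features=3, seed=0, shift=None):
    """Feature table with class-shifted Gaussian features."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in counts.items():
        mu = (shift or {}).get(label, 0.0)
        for _ in range(n):
            rows.append([label] + list(rng.normal(loc=mu,
                                                  size=n_features)))
    df = pd.DataFrame(rows, columns=["label"]
                      + [f"f{i}" for i in range(n_features)])
    df.insert(0, "participant", "p1")
    df.insert(1, "session", "s1")
    df.insert(2, "window", range(len(df)))
    df.insert(3, "start_s", 0.0)
    return df


class TestBalancing:
    def test_undersamples_unknown_resamples_minorities(self):
        table = make_table({"unknown": 1000, "flap": 100, "rock": 50})
        out = rm.balance_training_set(table, seed=0)
        assert out["label"].value_counts().to_dict() == \
            {"unknown": 100, "flap": 100, "rock": 100}

    def test_already_balanced_unchanged_counts(self):
        table = make_table({"unknown": 80, "flap": 80, "rock": 80})
        out = rm.balance_training_set(table, seed=1)
        assert out["label"].value_counts().to_dict() == \
            {"unknown": 80, "flap": 80, "rock": 80}

    def test_deterministic_given_seed(self):
        table = make_table({"unknown": 300, "flap": 40})
        a = rm.balance_training_set(table, seed=5)
        b = rm.balance_training_set(table, seed=5)
        assert a.equals(b)

    def test_unknown_rows_subset_of_input(self):
        table = make_table({"unknown": 500, "flap": 60})
        out = rm.balance_training_set(table, seed=2)
        in_windows = set(table[table.label == "unknown"]["window"])
        out_unknown = out[out.label == "unknown"]["window"]
        assert set(out_unknown) <= in_windows
        assert out_unknown.is_unique  # without replacement

    def test_empty_class_dropped_with_warning(self):
        table = make_table({"unknown": 50, "flap": 20})
        with pytest.warns(UserWarning, match="rock"):
            out = rm.balance_training_set(table, seed=0)
        assert set(out["label"]) == {"unknown", "flap"}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rm.balance_training_set(make_table({"unknown": 10}), seed=0)


class TestZScore:
    def test_closed_form_population_sd(self):
        table = make_table({"flap": 3})
        table["f0"] = [1.0, 2.0, 3.0]
        params = rm.fit_zscore(table)
        out = rm.apply_zscore(params, table)
        np.testing.assert_allclose(out["f0"],
                                   [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-8)

    def test_constant_column_maps_to_zero(self):
        table = make_table({"flap": 4})
        table["f1"] = 7.0
        out = rm.apply_zscore(rm.fit_zscore(table), table)
        assert (out["f1"] == 0.0).all()

    def test_refit_after_apply_is_identity(self):
        table = make_table({"flap": 20, "rock": 20}, seed=3)
        out = rm.apply_zscore(rm.fit_zscore(table), table)
        params = rm.fit_zscore(out)
        np.testing.assert_allclose(params.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(params.std, 1.0, atol=1e-12)

    def test_test_rows_use_training_parameters(self):
        train = make_table({"flap": 10}, seed=1)
        test = make_table({"flap": 5}, seed=2)
        params = rm.fit_zscore(train)
        out = rm.apply_zscore(params, test)
        expected = (test["f0"] - params.mean["f0"]) / params.std["f0"]
        np.testing.assert_allclose(out["f0"], expected)


class TestTrainPredict:
    @pytest.mark.parametrize("kind", rm.models.MODEL_KINDS)
    def test_separable_classes_perfect_training_accuracy(self, kind):
        table = make_table({"flap": 40, "rock": 40}, seed=4,
                           shift={"flap": -5.0, "rock": 5.0})
        clf = rm.train(rm.ModelConfig(kind), table, seed=0)
        assert (rm.predict(clf, table) == table["label"]).all()

    def test_pure_tree_memorizes_training_rows(self):
        table = make_table({"flap": 30, "rock": 30, "unknown": 30}, seed=5)
        clf = rm.train(rm.ModelConfig("decision_tree"), table, seed=0)
        assert (rm.predict(clf, table) == table["label"]).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            rm.train(rm.ModelConfig("decision_tree"),
                     make_table({"flap": 10}), seed=0)

    def test_training_on_tainted_table_rejected(self):
        table = rm.mark_test(make_table({"flap": 10, "rock": 10}))
        with pytest.raises(ValueError, match="training rows"):
            rm.train(rm.ModelConfig("decision_tree"), table, seed=0)
        with pytest.raises(ValueError, match="training rows"):
            rm.balance_training_set(table, seed=0)
        with pytest.raises(ValueError, match="training rows"):
            rm.fit_zscore(table)

    def test_deterministic_given_seed(self):
        table = make_table({"flap": 60, "rock": 60}, seed=6,
                           shift={"rock": 1.0})
        test = make_table({"flap": 30, "rock": 30}, seed=7,
                          shift={"rock": 1.0})
        for kind in rm.models.MODEL_KINDS:
            clf1 = rm.train(rm.ModelConfig(kind), table, seed=9)
            clf2 = rm.train(rm.ModelConfig(kind), table, seed=9)
            np.testing.assert_array_equal(rm.predict(clf1, test),
                                          rm.predict(clf2, test))

    def test_forest_matches_reference_implementation(self, tiny_cohort):
        """Held-out accuracy within 0.05 of sklearn's random forest."""
        table = rm.build_feature_table(
            tiny_cohort[:2], rm.SENSOR_POSITIONS, rm.SegmentationConfig(),
            rm.RQAConfig(0.232))
        two = table[table.label.isin(["flap", "unknown"])]
        two = two.groupby("label", group_keys=False).head(100)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(two))
        train_t = two.iloc[idx[:140]].reset_index(drop=True)
        test_t = two.iloc[idx[140:]].reset_index(drop=True)
        cols = rm.feature_columns(train_t)

        clf = rm.train(rm.ModelConfig("random_forest", n_trees=100),
                       train_t, seed=0)
        acc_ours = np.mean(rm.predict(clf, test_t) == test_t["label"])

        ref = RandomForestClassifier(n_estimators=100, criterion="gini",
                                     max_features="sqrt", random_state=0)
        ref.fit(train_t[cols], train_t["label"])
        acc_ref = np.mean(ref.predict(test_t[cols]) == test_t["label"])
        assert abs(acc_ours - acc_ref) <= 0.05

    def test_forest_accuracy_grows_with_trees(self):
        improvements = 0
        for seed in range(10):
            train_t = make_table({"flap": 80, "rock": 80}, seed=seed,
                                 shift={"rock": 0.8})
            test_t = make_table({"flap": 80, "rock": 80}, seed=seed + 100,
                                shift={"rock": 0.8})
            accs = {}
            for n in (10, 250):
                clf = rm.train(rm.ModelConfig("random_forest", n_trees=n),
                               train_t, seed=seed)
                accs[n] = np.mean(rm.predict(clf, test_t)
                                  == test_t["label"])
            improvements += accs[250] >= accs[10]
        assert improvements >= 6


class TestPermutationImportance:
    def _fit_forest(self, table, seed=0, n_trees=60):
        return rm.train(rm.ModelConfig("random_forest", n_trees=n_trees),
                        table, seed=seed)

    def test_noise_feature_ranked_last(self):
        last = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = make_table({"flap": 80, "rock": 80}, seed=seed,
                               shift={"rock": 2.0})
            table["noise"] = rng.normal(size=len(table))
            ranking = rm.permutation_importance(
                self._fit_forest(table, seed), seed=seed)
            last += ranking[-1][0] == "noise"
        assert last >= 18

    def test_duplicated_feature_dilutes_importance(self):
        wins = 0
        for seed in range(11):
            rng = np.random.default_rng(seed)
            base = make_table({"flap": 70, "rock": 70}, n_features=1,
                              seed=seed, shift={"rock": 1.5})
            base["n0"] = rng.normal(size=len(base))
            base["n1"] = rng.normal(size=len(base))
            lone = dict(rm.permutation_importance(
                self._fit_forest(base, seed), seed=seed))
            dup = base.copy()
            dup["f0_copy"] = dup["f0"]
            dup_scores = dict(rm.permutation_importance(
                self._fit_forest(dup, seed), seed=seed))
            wins += lone["f0"] >= max(dup_scores["f0"],
                                      dup_scores["f0_copy"])
        assert wins >= 6

    def test_single_feature_ranked_first(self):
        table = make_table({"flap": 40, "rock": 40}, n_features=1,
                           seed=1, shift={"rock": 2.0})
        ranking = rm.permutation_importance(self._fit_forest(table), seed=0)
        assert ranking[0][0] == "f0"

    def test_requires_oob_bookkeeping(self):
        table = make_table({"flap": 20, "rock": 20})
        clf = rm.train(rm.ModelConfig("decision_tree"), table, seed=0)
        with pytest.raises(ValueError, match="out-of-bag"):
            rm.permutation_importance(clf)


class TestSelectHyperparameters:
    def test_single_point_grid(self):
        table = make_table({"flap": 40, "rock": 40, "unknown": 40},
                           shift={"rock": 2.0})
        folds = lambda eps: [(table, table)]
        eps, config, score = rm.select_hyperparameters(
            [rm.ModelConfig("decision_tree")], [0.5], folds, seed=0)
        assert (eps, config.kind) == (0.5, "decision_tree")

    def test_strictly_better_epsilon_selected(self):
        good = make_table({"flap": 50, "rock": 50, "unknown": 50},
                          shift={"rock": 3.0, "flap": -3.0}, seed=1)
        bad = good.copy()
        rng = np.random.default_rng(2)
        for c in rm.feature_columns(bad):
            bad[c] = rng.normal(size=len(bad))  # uninformative features

        def folds(eps):
            table = good if eps == 0.25 else bad
            half = len(table) // 2
            return [(table.iloc[:half], table.iloc[half:])]

        eps, _, _ = rm.select_hyperparameters(
            [rm.ModelConfig("decision_tree")], [0.5, 0.25], folds, seed=0)
        assert eps == 0.25

    def test_selected_epsilon_matches_exhaustive_oracle(self, tiny_cohort):
        """CV pick agrees with brute-force evaluation over the same folds."""
        session_a, session_b = tiny_cohort[0], tiny_cohort[1]
        grid = [0.549, 0.232, 0.098, 0.041]
        tables = {
            eps: (rm.build_feature_table([session_a], rm.SENSOR_POSITIONS,
                                         rm.SegmentationConfig(),
                                         rm.RQAConfig(eps)),
                  rm.build_feature_table([session_b], rm.SENSOR_POSITIONS,
                                         rm.SegmentationConfig(),
                                         rm.RQAConfig(eps)))
            for eps in grid
        }
        folds = lambda eps: [tables[eps]]
        config = rm.ModelConfig("decision_tree")
        eps_sel, _, _ = rm.select_hyperparameters([config], grid, folds,
                                                  seed=0)

        # independent exhaustive loop over the same grid
        scores = {}
        for eps in grid:
            tr, va = tables[eps]
            pred = rm.models.fit_predict(config, tr, va, seed=0,
                                         balance_seed=0)
            scores[eps] = np.mean(pred == va["label"])
        best = max(scores.values())
        oracle_best = [e for e in grid if scores[e] >= best]
        idx = grid.index(eps_sel)
        assert any(abs(grid.index(e) - idx) <= 1 for e in oracle_best)

    def test_ties_break_to_smaller_epsilon_and_capacity(self):
        table = make_table({"flap": 30, "rock": 30}, shift={"rock": 9.0})
        folds = lambda eps: [(table, table)]
        eps, config, _ = rm.select_hyperparameters(
            [rm.ModelConfig("random_forest", n_trees=n)
             for n in (250, 100)],
            [0.5, 0.25], folds, seed=0)
        assert eps == 0.25
        assert config.n_trees == 100
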