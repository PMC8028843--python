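"""Split plans, training harness, confusion metrics and ablation wiring."""

import itertools

import numpy as np
import pandas as pd
import pytest

import riceyield as ry
from riceyield.split_eval import (
    CLASSES,
    DesignError,
    TrainingError,
    ModelConfig,
    precision_recall_from_confusion,
)
from conftest import make_fieldmap

SMALL_GRID = {"max_depth": [2], "learning_rate": [0.3], "n_estimators": [40]}


def make_synthetic_features(
    n_plots_per_class=3, n_per_plot=12, separation=5.0, seed=0, n_features=4
):
    """Labelled features with class-wise Gaussian clusters; separation in
    units of the within-class standard deviation."""
    rng = np.random.default_rng(seed)
    rows = []
    plot_id = 0
    for ci, cls in enumerate(CLASSES):
        for _ in range(n_plots_per_class):
            X = rng.normal(ci * separation, 1.0, size=(n_per_plot, n_features))
            for j in range(n_per_plot):
                rows.append(
                    {
                        "plot_id": plot_id,
                        "px_row": j,
                        "px_col": j,
                        "line_id": f"L{plot_id}",
                        "replicate": 1,
                        **{f"f{k}": X[j, k] for k in range(n_features)},
                        "label": cls,
                    }
                )
            plot_id += 1
    return pd.DataFrame(rows)


class TestIntralineSplits:
    def test_three_replicate_holdout_plans(self, default_scene):
        _, fieldmap, _ = default_scene
        plans = ry.make_intraline_splits(fieldmap)
        assert len(plans) == 3
        for plan in plans:
            assert len(plan.test_plots) == 13
            assert not set(plan.train_plots) & set(plan.test_plots)

    def test_test_sets_partition_all_plots(self, default_scene):
        _, fieldmap, _ = default_scene
        plans = ry.make_intraline_splits(fieldmap)
        union = sorted(itertools.chain(*(p.test_plots for p in plans)))
        assert union == sorted(fieldmap.plots["plot_id"])

    def test_unequal_replicates_rejected(self, default_scene):
        _, fieldmap, _ = default_scene
        broken = ry.FieldMap(fieldmap.plots.iloc[:-1])
        with pytest.raises(DesignError, match="replicate"):
            ry.make_intraline_splits(broken)


class TestInterlineSplits:
    def test_study_class_sizes_give_56_plans(self, default_scene):
        _, fieldmap, _ = default_scene
        plans = ry.make_interline_splits(fieldmap)
        assert len(plans) == 56  # 2 x 7 x 4

    def test_single_line_classes_give_one_plan(self):
        fieldmap = make_fieldmap((1, 1, 1))
        assert len(ry.make_interline_splits(fieldmap)) == 1

    def test_one_test_line_per_class_and_disjoint(self, default_scene):
        _, fieldmap, _ = default_scene
        plots = fieldmap.plots.set_index("plot_id")
        for plan in ry.make_interline_splits(fieldmap):
            test_lines = plots.loc[list(plan.test_plots)]
            per_class = test_lines.groupby("class_label")["line_id"].nunique()
            assert per_class.to_dict() == {"A": 1, "B": 1, "C": 1}
            # all replicates of a held-out line are in test, none in train
            train_lines = set(plots.loc[list(plan.train_plots), "line_id"])
            assert not set(test_lines["line_id"]) & train_lines

    @pytest.mark.parametrize(
        "sizes", [(1, 1, 1), (2, 1, 1), (2, 3, 1), (2, 3, 4), (4, 4, 4)]
    )
    def test_plan_count_equals_product_of_class_sizes(self, sizes):
        fieldmap = make_fieldmap(sizes)
        plans = ry.make_interline_splits(fieldmap)
        by_class = fieldmap.lines_by_class()
        expected = list(
            itertools.product(*(by_class[c] for c in CLASSES))
        )
        assert len(plans) == len(expected) == int(np.prod(sizes))

    def test_empty_class_rejected(self):
        fieldmap = make_fieldmap((1, 1, 1))
        no_c = ry.FieldMap(
            fieldmap.plots[fieldmap.plots["class_label"] != "C"]
        )
        with pytest.raises(DesignError, match="C"):
            ry.make_interline_splits(no_c)


class TestMetrics:
    def test_hand_built_confusion(self):
        cm = np.array([[5, 0, 0], [2, 3, 0], [0, 0, 4]])
        precision, recall = precision_recall_from_confusion(cm)
        assert precision["A"] == pytest.approx(5 / 7)
        assert recall["A"] == pytest.approx(1.0)
        assert precision["B"] == pytest.approx(1.0)
        assert recall["B"] == pytest.approx(3 / 5)

    def test_zero_column_precision_is_zero(self):
        cm = np.array([[0, 3, 0], [0, 5, 0], [0, 1, 2]])
        precision, _ = precision_recall_from_confusion(cm)
        assert precision["A"] == 0.0

    def test_matches_brute_force_pair_counting(self, rng):
        true = rng.choice(list(CLASSES), size=200)
        pred = rng.choice(list(CLASSES), size=200)
        cm = np.zeros((3, 3), dtype=int)
        for t, p in zip(true, pred):
            cm[CLASSES.index(t), CLASSES.index(p)] += 1
        precision, recall = precision_recall_from_confusion(cm)
        for cls in CLASSES:
            tp = np.sum((true == cls) & (pred == cls))
            pp = np.sum(pred == cls)
            ap = np.sum(true == cls)
            assert precision[cls] == pytest.approx(tp / pp if pp else 0.0)
            assert recall[cls] == pytest.approx(tp / ap if ap else 0.0)


@pytest.fixture(scope="module")
def separable():
    features = make_synthetic_features(separation=8.0)
    plots = features["plot_id"].unique()
    # hold out one plot of each class
    plan = ry.SplitPlan(
        "toy", tuple(np.delete(plots, [2, 5, 8])), tuple(plots[2::3]),
        "interline",
    )
    return features, plan


class TestTrainClassifier:

    def test_separable_data_trains_to_perfect_accuracy(self, separable):
        features, plan = separable
        config = ModelConfig(grid=SMALL_GRID, seed=0)
        fitted = ry.train_classifier(features, plan, config)
        train = features[features["plot_id"].isin(plan.train_plots)]
        assert (fitted.predict(train) == train["label"]).all()

    def test_deterministic_given_seed(self, separable):
        features, plan = separable
        config = ModelConfig(grid=SMALL_GRID, seed=5)
        test = features[features["plot_id"].isin(plan.test_plots)]
        a = ry.train_classifier(features, plan, config).predict(test)
        b = ry.train_classifier(features, plan, config).predict(test)
        assert np.array_equal(a, b)

    def test_grid_search_selects_point_from_grid(self, separable):
        features, plan = separable
        grid = {"max_depth": [2, 4], "learning_rate": [0.3], "n_estimators": [30]}
        fitted = ry.train_classifier(
            features, plan, ModelConfig(grid=grid, seed=0)
        )
        assert fitted.best_params["max_depth"] in grid["max_depth"]

    def test_single_class_training_rejected(self, separable):
        features, _ = separable
        a_plots = features.loc[features["label"] == "A", "plot_id"].unique()
        other = features.loc[features["label"] != "A", "plot_id"].unique()
        plan = ry.SplitPlan("bad", tuple(a_plots), tuple(other), "interline")
        with pytest.raises(TrainingError, match="single-class"):
            ry.train_classifier(features, plan, ModelConfig(grid=SMALL_GRID))

    def test_no_leakage_from_test_rows(self, separable):
        """Corrupting test-set features must not change the fitted model."""
        features, plan = separable
        config = ModelConfig(grid=SMALL_GRID, seed=1)
        test_mask = features["plot_id"].isin(plan.test_plots)
        probe = features.loc[~test_mask].copy()
        before = ry.train_classifier(features, plan, config)
        corrupted = features.copy()
        feat_cols = ry.feature_columns(features)
        corrupted.loc[test_mask, feat_cols] = 1e6
        after = ry.train_classifier(corrupted, plan, config)
        assert np.array_equal(before.predict(probe), after.predict(probe))


class TestEvaluate:
    def test_perfect_predictions_give_unit_metrics(self):
        features = make_synthetic_features(separation=6.0)
        plots = features["plot_id"].unique()
        plan = ry.SplitPlan(
            "toy", tuple(plots[::2]), tuple(plots[1::2]), "intraline"
        )

        class Oracle:  # predicts the true class code from the cluster mean
            def predict(self, X):
                return np.clip(np.round(X.mean(axis=1) / 6.0), 0, 2).astype(int)

        fitted = ry.FittedModel(Oracle(), {}, ry.feature_columns(features))
        report = ry.evaluate(fitted, features, plan)
        for cls in CLASSES:
            assert report.precision[cls] == 1.0
            assert report.recall[cls] == 1.0

    def test_confusion_total_equals_test_samples(self):
        features = make_synthetic_features(separation=0.5, seed=3)
        plots = features["plot_id"].unique()
        plan = ry.SplitPlan(
            "toy", tuple(plots[::2]), tuple(plots[1::2]), "intraline"
        )
        fitted = ry.train_classifier(
            features, plan, ModelConfig(grid=SMALL_GRID, seed=0)
        )
        report = ry.evaluate(fitted, features, plan)
        n_test = features["plot_id"].isin(plan.test_plots).sum()
        assert report.n_test == n_test

    def test_plot_level_majority_vote(self):
        features = make_synthetic_features(separation=10.0)
        plots = features["plot_id"].unique()
        plan = ry.SplitPlan(
            "toy", tuple(plots[::2]), tuple(plots[1::2]), "intraline"
        )
        fitted = ry.train_classifier(
            features, plan, ModelConfig(grid=SMALL_GRID, seed=0)
        )
        report = ry.evaluate(fitted, features, plan, level="plot")
        assert report.n_test == len(plan.test_plots)


class TestNullBehaviour:
    def test_pure_noise_accuracy_near_chance(self):
        """On feature noise with balanced classes, interline-style test
        accuracy stays within 3 sigma of the majority-class rate."""
        accs = []
        for seed in range(10):
            features = make_synthetic_features(
                separation=0.0, seed=seed, n_per_plot=10
            )
            plots = features["plot_id"].unique()
            plan = ry.SplitPlan(
                "null", tuple(plots[::2]), tuple(plots[1::2]), "interline"
            )
            fitted = ry.train_classifier(
                features, plan, ModelConfig(grid=SMALL_GRID, seed=seed)
            )
            accs.append(ry.evaluate(fitted, features, plan).accuracy)
        mean = np.mean(accs)
        sigma = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 1 / 3) <= 3 * sigma + 0.05


class TestRunAblation:
    def test_report_bookkeeping(self):
        fw = make_synthetic_features(separation=4.0)
        fw["lodging_index"] = (fw["label"] == "A").astype(int) * 3
        fo = fw.drop(columns="lodging_index")
        plots = fw["plot_id"].unique()
        plans = [
            ry.SplitPlan("p1", tuple(np.delete(plots, [2, 5, 8])),
                         tuple(plots[2::3]), "interline"),
            ry.SplitPlan("p2", tuple(np.delete(plots, [0, 3, 6])),
                         tuple(plots[0::3]), "interline"),
        ]
        reports = ry.run_ablation(
            fw, fo, plans, ModelConfig(grid=SMALL_GRID),
            learners=("xgboost", "naive_bayes"),
        )
        assert len(reports) == len(plans) * 3 * 2
        keys = {(r.plan_id, r.condition, r.learner) for r in reports}
        assert len(keys) == len(reports)

    def test_row_mismatch_rejected(self):
        fw = make_synthetic_features()
        fw["lodging_index"] = 0
        fo = fw.drop(columns="lodging_index").iloc[:-1]
        with pytest.raises(DesignError, match="row"):
            ry.run_ablation(fw, fo, [], ModelConfig(grid=SMALL_GRID))

    def test_summary_contains_per_plan_and_mean_rows(self):
        fw = make_synthetic_features(separation=4.0)
        fw["lodging_index"] = (fw["label"] == "A").astype(int) * 3
        fo = fw.drop(columns="lodging_index")
        plots = fw["plot_id"].unique()
        plans = [ry.SplitPlan("p1", tuple(np.delete(plots, [2, 5, 8])),
                              tuple(plots[2::3]), "interline")]
        reports = ry.run_ablation(fw, fo, plans, ModelConfig(grid=SMALL_GRID))
        summary = ry.summarize_reports(reports)
        assert set(summary["plan"]) == {"p1", "mean"}
        assert set(summary["condition"]) == set(
            ("with_lodging", "without_lodging", "lodging_only")
        )
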