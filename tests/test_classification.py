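import numpy as np
import pandas as pd
import pytest

from fluoroperf.classification import (
    ROIDataset,
    aggregate_patient,
    evaluate,
    load_model,
    patient_folds,
    predict_roi,
    save_model,
    train_ensemble,
)
from fluoroperf.datasets import make_milestone_dataset

# small grid keeps the unit tests quick; full grid runs in acceptance
SMALL_SPACE = [
    {"family": "bagged", "n_estimators": 50, "max_depth": 4},
    {"family": "boosted", "n_estimators": 50, "max_depth": 2, "learning_rate": 0.1},
]


@pytest.fixture(scope="module")
def separable_df():
    return make_milestone_dataset(n_patients=16, rois_per_patient=4, seed=11)


@pytest.fixture(scope="module")
def separable_dataset(separable_df):
    return ROIDataset.from_features_frame(separable_df)


@pytest.fixture(scope="module")
def trained(separable_dataset):
    return train_ensemble(separable_dataset, search_space=SMALL_SPACE, seed=5)


class TestROIDataset:
    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing values"):
            ROIDataset(df, pd.Series(["benign", "cancer"]), pd.Series(["p1", "p2"]))

    def test_unknown_labels_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unknown class"):
            ROIDataset(df, pd.Series(["benign", "odd"]), pd.Series(["p1", "p2"]))

    def test_balance_summary(self, separable_dataset):
        balance = separable_dataset.class_balance()
        assert balance["benign"] == balance["cancer"] == 32


class TestTrainEnsemble:
    def test_single_class_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        ds = ROIDataset(df, pd.Series(["benign"] * 10), pd.Series([f"p{i}" for i in range(10)]))
        with pytest.raises(ValueError, match="2 classes"):
            train_ensemble(ds, search_space=SMALL_SPACE)

    def test_fewer_patients_than_folds_rejected(self):
        df = pd.DataFrame({"a": np.arange(4.0)})
        ds = ROIDataset(
            df, pd.Series(["benign", "cancer"] * 2), pd.Series(["p1", "p1", "p2", "p2"])
        )
        with pytest.raises(ValueError, match="patients"):
            train_ensemble(ds, n_folds=5, search_space=SMALL_SPACE)

    def test_separable_dataset_cv_accuracy(self, trained, separable_dataset):
        assert trained.cv_mean_accuracy >= 0.95
        assert len(trained.cv_fold_accuracy) == 5
        # independent nearest-centroid oracle on the same data
        X = separable_dataset.features.to_numpy()
        y = separable_dataset.labels.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        centroids = {c: Xs[y == c].mean(0) for c in ("benign", "cancer")}
        calls = np.where(
            np.linalg.norm(Xs - centroids["cancer"], axis=1)
            < np.linalg.norm(Xs - centroids["benign"], axis=1),
            "cancer",
            "benign",
        )
        assert (calls == y).mean() >= 0.95

    def test_label_permutation_is_chance_level(self, separable_df):
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(5):
            df = separable_df.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            try:
                ds = ROIDataset.from_features_frame(df)
                model = train_ensemble(ds, search_space=SMALL_SPACE[:1], seed=1)
                accs.append(model.cv_mean_accuracy)
            except ValueError:
                continue
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_row_shuffle_does_not_change_cv(self, separable_df):
        ds1 = ROIDataset.from_features_frame(separable_df)
        shuffled = separable_df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        ds2 = ROIDataset.from_features_frame(shuffled)
        m1 = train_ensemble(ds1, search_space=SMALL_SPACE[:1], seed=5)
        m2 = train_ensemble(ds2, search_space=SMALL_SPACE[:1], seed=5)
        assert m1.cv_mean_accuracy == pytest.approx(m2.cv_mean_accuracy, abs=1e-12)

    def test_noise_degrades_monotonically(self):
        # mean CV accuracy must not increase with simulated sensor noise;
        # moderately separated classes so the top noise level actually bites
        from fluoroperf.curve_features import FeatureConfig
        from fluoroperf.synthetic_data import KineticParams

        kinetics = {
            "normal": KineticParams(t0=8.0, alpha=4.0, beta=3.0, amplitude=400.0, baseline=120.0),
            "benign": KineticParams(t0=9.0, alpha=4.5, beta=3.2, amplitude=420.0, baseline=120.0),
            "malignant": KineticParams(t0=7.0, alpha=3.5, beta=2.6, amplitude=450.0, baseline=120.0),
        }
        config = FeatureConfig(onset_threshold=0.1, onset_sustain_seconds=1.0)
        accs = []
        for noise in (2.0, 120.0, 300.0):
            df = make_milestone_dataset(
                n_patients=10, rois_per_patient=3, class_kinetics=kinetics,
                noise_sd=noise, param_spread=1.0, seed=21, feature_config=config,
            )
            ds = ROIDataset.from_features_frame(df)
            accs.append(train_ensemble(ds, search_space=SMALL_SPACE[:1], seed=2).cv_mean_accuracy)
        assert accs[0] >= accs[1] >= accs[2] - 1e-9
        assert accs[2] < accs[0]  # top level genuinely degrades

    def test_patient_folds_do_not_split_patients(self, separable_dataset):
        folds = patient_folds(separable_dataset.patient_ids, 5, seed=0)
        per_patient = pd.Series(folds).groupby(separable_dataset.patient_ids.to_numpy())
        assert all(g.nunique() == 1 for _, g in per_patient)


class TestPredict:
    def test_training_point_called_confidently(self, trained, separable_df):
        cancer_rows = separable_df[separable_df["label"] == "cancer"]
        preds = predict_roi(trained, cancer_rows)
        assert (preds["probability"] > 0.5).mean() > 0.9

    def test_missing_column_is_schema_error(self, trained, separable_df):
        broken = separable_df.drop(columns=["com"])
        with pytest.raises(ValueError, match="schema mismatch.*com"):
            predict_roi(trained, broken)

    def test_deterministic(self, trained, separable_df):
        a = predict_roi(trained, separable_df)
        b = predict_roi(trained, separable_df)
        pd.testing.assert_frame_equal(a, b)

    def test_save_load_round_trip(self, trained, separable_df, tmp_path):
        save_model(trained, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        assert back.feature_names == trained.feature_names
        pd.testing.assert_frame_equal(
            predict_roi(back, separable_df), predict_roi(trained, separable_df)
        )


class TestAggregatePatient:
    @pytest.mark.parametrize("rule", ["any", "majority"])
    def test_all_benign(self, rule):
        assert aggregate_patient(["benign", "benign"], rule) == "benign"

    def test_tie_goes_to_cancer(self):
        assert aggregate_patient(["benign", "cancer"], "any") == "cancer"
        assert aggregate_patient(["benign", "cancer"], "majority") == "cancer"

    def test_rule_contrast(self):
        calls = ["benign", "benign", "cancer"]
        assert aggregate_patient(calls, "any") == "cancer"
        assert aggregate_patient(calls, "majority") == "benign"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no ROI calls"):
            aggregate_patient([])


class TestEvaluate:
    def test_biopsy_as_classifier(self):
        # 7 cancers all called benign, 7 benign all called benign
        truth = pd.Series(["cancer"] * 7 + ["benign"] * 7, index=range(14))
        calls = pd.Series(["benign"] * 14, index=range(14))
        res = evaluate(calls, truth)
        assert (res.accuracy_rounded, res.sensitivity_rounded, res.specificity_rounded) == (
            50, 0, 100,
        )

    def test_patient_level_confusion(self):
        # TP=7, FN=0, TN=5, FP=2 -> accuracy 12/14 ~ 86%
        truth = pd.Series(["cancer"] * 7 + ["benign"] * 7, index=range(14))
        calls = pd.Series(["cancer"] * 7 + ["cancer"] * 2 + ["benign"] * 5, index=range(14))
        res = evaluate(calls, truth)
        assert (res.tp, res.fn, res.tn, res.fp) == (7, 0, 5, 2)
        assert res.accuracy_rounded == 86
        assert res.sensitivity_rounded == 100

    def test_perfect_predictions(self):
        truth = pd.Series(["cancer", "benign"] * 5, index=range(10))
        res = evaluate(truth.copy(), truth)
        assert (res.accuracy_rounded, res.sensitivity_rounded, res.specificity_rounded) == (
            100, 100, 100,
        )

    def test_id_mismatch_rejected(self):
        truth = pd.Series(["cancer"], index=["a"])
        calls = pd.Series(["cancer"], index=["b"])
        with pytest.raises(ValueError, match="unit ids"):
            evaluate(calls, truth)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            truth = pd.Series(rng.choice(["benign", "cancer"], n), index=range(n))
            calls = pd.Series(rng.choice(["benign", "cancer"], n), index=range(n))
            res = evaluate(calls, truth)
            # naive loop oracle
            tp = fp = tn = fn = 0
            for i in range(n):
                if truth[i] == "cancer":
                    tp, fn = tp + (calls[i] == "cancer"), fn + (calls[i] == "benign")
                else:
                    tn, fp = tn + (calls[i] == "benign"), fp + (calls[i] == "cancer")
            assert (res.tp, res.fp, res.tn, res.fn) == (tp, fp, tn, fn)
            assert res.accuracy == pytest.approx(100 * (tp + tn) / n)
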