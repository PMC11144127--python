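"""Ensemble classification of ROI milestone features with grouped CV.

The "optimizable ensemble" is realized as a seeded hyperparameter search
over bagged (random forest) and gradient-boosted decision-tree ensembles,
scored by mean patient-grouped k-fold cross-validation accuracy;
standardization constants are fitted on training folds only. ROI calls are
aggregated to a patient-level benign/cancer decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ROIDataset",
    "EnsembleModel",
    "PredictionResult",
    "default_search_space",
    "train_ensemble",
    "predict_roi",
    "aggregate_patient",
    "evaluate",
    "save_model",
    "load_model",
]

POSITIVE_CLASS = "cancer"
CLASSES = ("benign", "cancer")


@dataclass
class ROIDataset:
    """Feature matrix with per-ROI labels and patient ids."""

    features: pd.DataFrame
    labels: pd.Series
    patient_ids: pd.Series

    def __post_init__(self) -> None:
        if self.features.empty:
            raise ValueError("empty feature matrix")
        if len(self.labels) != len(self.features) or len(self.patient_ids) != len(self.features):
            raise ValueError("labels/patient_ids must align with features")
        if self.features.isna().any().any():
            bad = self.features.columns[self.features.isna().any()].tolist()
            raise ValueError(f"missing values in feature column(s) {bad}")
        bad = set(self.labels.unique()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        if self.patient_ids.isna().any():
            raise ValueError("every ROI row needs a patient id")

    @property
    def n_classes(self) -> int:
        return self.labels.nunique()

    def class_balance(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    @classmethod
    def from_features_frame(
        cls, df: pd.DataFrame, feature_columns: list[str] | None = None
    ) -> "ROIDataset":
        """Build from a features CSV frame (``label`` column holds the class)."""
        if feature_columns is None:
            feature_columns = [
                c for c in df.columns
                if c not in ("roi_id", "label", "patient_id") and df[c].notna().all()
            ]
        return cls(
            features=df[feature_columns].reset_index(drop=True),
            labels=df["label"].reset_index(drop=True),
            patient_ids=df["patient_id"].astype(str).reset_index(drop=True),
        )


def default_search_space() -> list[dict]:
    """Seedable grid over bagged and boosted tree ensembles."""
    space: list[dict] = []
    for n in (50, 100, 200):
        for depth in (2, 4, 8):
            space.append({"family": "bagged", "n_estimators": n, "max_depth": depth})
            for lr in (0.05, 0.1, 0.3):
                space.append(
                    {
                        "family": "boosted",
                        "n_estimators": n,
                        "max_depth": depth,
                        "learning_rate": lr,
                    }
                )
    return space


def _make_pipeline(config: dict, seed: int) -> Pipeline:
    if config["family"] == "bagged":
        est = RandomForestClassifier(
            n_estimators=config["n_estimators"],
            max_depth=config["max_depth"],
            random_state=seed,
        )
    elif config["family"] == "boosted":
        est = GradientBoostingClassifier(
            n_estimators=config["n_estimators"],
            max_depth=config["max_depth"],
            learning_rate=config["learning_rate"],
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown ensemble family {config['family']!r}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def patient_folds(patient_ids: pd.Series, n_folds: int, seed: int) -> np.ndarray:
    """Seed-fixed fold assignment keyed by patient: no patient spans folds."""
    patients = np.array(sorted(patient_ids.unique()))
    if len(patients) < n_folds:
        raise ValueError(
            f"need >= {n_folds} patients for {n_folds}-fold grouped CV, got {len(patients)}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    fold_of_patient = {p: i % n_folds for i, p in enumerate(patients)}
    return patient_ids.map(fold_of_patient).to_numpy()


@dataclass
class EnsembleModel:
    """Fitted ensemble with its CV report and training schema."""

    pipeline: Pipeline
    family: str
    params: dict
    feature_names: list[str]
    seed: int
    cv_fold_accuracy: list[float]
    cv_mean_accuracy: float
    classes: tuple[str, ...] = CLASSES


def train_ensemble(
    dataset: ROIDataset,
    n_folds: int = 5,
    search_space: list[dict] | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Search the ensemble grid by mean grouped-CV accuracy and refit the best.

    Folds are keyed by patient id (seed-fixed) so no patient's ROIs span a
    train/test boundary; the scaler is refitted inside every training fold.
    """
    if dataset.n_classes < 2:
        raise ValueError("training needs at least 2 classes")
    space = search_space if search_space is not None else default_search_space()
    folds = patient_folds(dataset.patient_ids, n_folds, seed)
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels.to_numpy()

    best: tuple[float, dict, list[float]] | None = None
    for config in space:
        accs = []
        for k in range(n_folds):
            test = folds == k
            if not test.any() or test.all():
                continue
            pipe = _make_pipeline(config, seed)
            pipe.fit(X[~test], y[~test])
            accs.append(float((pipe.predict(X[test]) == y[test]).mean()))
        mean_acc = float(np.mean(accs))
        if best is None or mean_acc > best[0]:
            best = (mean_acc, config, accs)

    mean_acc, config, accs = best
    pipeline = _make_pipeline(config, seed)
    pipeline.fit(X, y)
    return EnsembleModel(
        pipeline=pipeline,
        family=config["family"],
        params={k: v for k, v in config.items() if k != "family"},
        feature_names=list(dataset.features.columns),
        seed=seed,
        cv_fold_accuracy=accs,
        cv_mean_accuracy=mean_acc,
    )


def predict_roi(
    model: EnsembleModel, features: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-ROI cancer probability and hard call.

    ``features`` must carry exactly the training feature columns (extra
    metadata columns are ignored); a missing column is a schema error.
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch: missing column(s) {missing}")
    X = features[model.feature_names].to_numpy(dtype=float)
    classes = list(model.pipeline.classes_)
    prob = model.pipeline.predict_proba(X)[:, classes.index(POSITIVE_CLASS)]
    return pd.DataFrame(
        {
            "probability": prob,
            "call": np.where(prob >= threshold, POSITIVE_CLASS, "benign"),
        },
        index=features.index,
    )


def aggregate_patient(roi_calls, rule: str = "any") -> str:
    """Combine one patient's ROI calls into a patient-level call.

    Rule "any": cancer if any ROI is called cancer. Rule "majority": modal
    call, ties resolved to cancer.
    """
    calls = list(roi_calls)
    if not calls:
        raise ValueError("no ROI calls to aggregate")
    bad = set(calls) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown calls {sorted(bad)}")
    n_cancer = sum(c == POSITIVE_CLASS for c in calls)
    if rule == "any":
        return POSITIVE_CLASS if n_cancer > 0 else "benign"
    if rule == "majority":
        return POSITIVE_CLASS if n_cancer >= len(calls) - n_cancer else "benign"
    raise ValueError(f"unknown aggregation rule {rule!r}")


@dataclass(frozen=True)
class PredictionResult:
    """Confusion counts and diagnostic metrics for one evaluation level."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float        # percent, unrounded
    sensitivity: float
    specificity: float
    accuracy_rounded: int
    sensitivity_rounded: int
    specificity_rounded: int
    n_units: int
    aggregation_rule: str | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_rounded": self.accuracy_rounded,
            "sensitivity_rounded": self.sensitivity_rounded,
            "specificity_rounded": self.specificity_rounded,
            "n_units": self.n_units, "aggregation_rule": self.aggregation_rule,
        }


def evaluate(
    calls: pd.Series, truth: pd.Series, aggregation_rule: str | None = None
) -> PredictionResult:
    """Confusion counts plus accuracy/sensitivity/specificity (percent).

    ``calls`` and ``truth`` must share the same unit index. Percentages are
    reported both unrounded and rounded to the nearest integer.
    """
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth must cover the same unit ids")
    truth = truth.loc[calls.index]
    is_pos = truth == POSITIVE_CLASS
    called_pos = calls == POSITIVE_CLASS
    tp = int((called_pos & is_pos).sum())
    fn = int((~called_pos & is_pos).sum())
    fp = int((called_pos & ~is_pos).sum())
    tn = int((~called_pos & ~is_pos).sum())
    n = tp + fn + fp + tn

    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")

    def _round(x: float) -> int:
        return int(round(x)) if np.isfinite(x) else -1

    return PredictionResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, sensitivity=sens, specificity=spec,
        accuracy_rounded=_round(acc),
        sensitivity_rounded=_round(sens),
        specificity_rounded=_round(spec),
        n_units=n,
        aggregation_rule=aggregation_rule,
    )


def save_model(model: EnsembleModel, path: str | Path) -> Path:
    """Persist the model as a single self-describing archive."""
    payload = {
        "format": "fluoroperf-ensemble-v1",
        "family": model.family,
        "params": model.params,
        "feature_names": model.feature_names,
        "seed": model.seed,
        "cv_fold_accuracy": model.cv_fold_accuracy,
        "cv_mean_accuracy": model.cv_mean_accuracy,
        "classes": model.classes,
        "pipeline": model.pipeline,
    }
    joblib.dump(payload, Path(path))
    return Path(path)


def load_model(path: str | Path) -> EnsembleModel:
    payload = joblib.load(Path(path))
    if payload.get("format") != "fluoroperf-ensemble-v1":
        raise ValueError(f"{path}: not a fluoroperf ensemble archive")
    return EnsembleModel(
        pipeline=payload["pipeline"],
        family=payload["family"],
        params=payload["params"],
        feature_names=payload["feature_names"],
        seed=payload["seed"],
        cv_fold_accuracy=payload["cv_fold_accuracy"],
        cv_mean_accuracy=payload["cv_mean_accuracy"],
        classes=tuple(payload["classes"]),
    )
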