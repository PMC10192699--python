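"""Frame-level classifier harness with grouped CV and ROC/AUC/EER metrics.

Frames from the same video are near-duplicates, so folds are formed by whole
videos (leave-one-video-out): each video's frames are scored by a model
fitted on all the other videos, and the pooled out-of-fold scores are
evaluated with the ROC curve, its area (AUC) and the equal error rate (EER,
the operating point where the false-positive and false-negative rates
coincide). The ablation harness sweeps classifier families against history
lengths, mirroring the experiment design used to select the final predictor
(a support-vector classifier with 13 frames of history).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig

__all__ = [
    "MODEL_NAMES",
    "RocCurve",
    "fit_classifier",
    "grouped_cv_scores",
    "roc_auc",
    "equal_error_rate",
    "history_ablation",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "logistic_regression",
    "svc",
    "gaussian_nb",
    "multinomial_nb",
    "kneighbors",
    "random_forest",
    "lightgbm",
    "xgboost",
)

#: models fed raw (non-negative) features instead of standardized ones
_UNSCALED = {"multinomial_nb"}


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points with their summary metrics."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    eer: float


def _base_estimator(model_name: str, seed: int):
    if model_name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model_name == "svc":
        # sigmoid-calibrated SVC: decision values mapped to probabilities
        return CalibratedClassifierCV(SVC(random_state=seed), method="sigmoid",
                                      ensemble=False)
    if model_name == "gaussian_nb":
        return GaussianNB()
    if model_name == "multinomial_nb":
        return MultinomialNB()
    if model_name == "kneighbors":
        return KNeighborsClassifier()
    if model_name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model_name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    if model_name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        )
    raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    model_name: str,
    seed: int = 0,
):
    """Fit a seeded scorer mapping feature vectors to anomaly probabilities.

    All models except multinomial_nb see per-fit standardized features
    (shift/scale learned from the training data); multinomial_nb requires the
    raw non-negative features.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if model_name in _UNSCALED:
        if (features < 0).any():
            raise ValueError("multinomial_nb requires non-negative features")
        model = Pipeline([("clf", _base_estimator(model_name, seed))])
    else:
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", _base_estimator(model_name, seed)),
            ]
        )
    model.fit(features, labels)
    return model


def score_anomaly(model, features: np.ndarray) -> np.ndarray:
    """Anomaly probability (class 1) per row, in [0, 1]."""
    proba = model.predict_proba(np.asarray(features, dtype=np.float64))
    classes = list(model.classes_)
    return proba[:, classes.index(1)]


def grouped_cv_scores(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    model_name: str,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-video-out scores for every frame.

    ``dataset`` is a sequence of per-video (feature matrix, frame labels).
    Returns pooled (scores, labels, group indices) aligned row-for-row; a
    training fold that collapses to one class is skipped with a warning and
    its video's frames are excluded from the pooled result.
    """
    if len(dataset) < 2:
        raise ValueError("grouped CV needs at least 2 videos")
    all_labels = np.concatenate([np.asarray(y, dtype=int) for _, y in dataset])
    if np.unique(all_labels).size < 2:
        raise ValueError("dataset contains a single class overall")

    scores_out, labels_out, groups_out = [], [], []
    for held_out in range(len(dataset)):
        X_tr = np.concatenate(
            [X for i, (X, _) in enumerate(dataset) if i != held_out]
        )
        y_tr = np.concatenate(
            [np.asarray(y, dtype=int) for i, (_, y) in enumerate(dataset) if i != held_out]
        )
        if np.unique(y_tr).size < 2:
            logger.warning(
                "skipping fold %d: training labels collapse to one class", held_out
            )
            continue
        model = fit_classifier(X_tr, y_tr, model_name, seed=config.seed)
        X_te, y_te = dataset[held_out]
        scores_out.append(score_anomaly(model, X_te))
        labels_out.append(np.asarray(y_te, dtype=int))
        groups_out.append(np.full(len(y_te), held_out))
    return (
        np.concatenate(scores_out),
        np.concatenate(labels_out),
        np.concatenate(groups_out),
    )


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve with AUC (trapezoidal, equal to pairwise concordance with
    ties counted 1/2) and interpolated EER."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thresholds = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(metrics.roc_auc_score(labels, scores))
    eer = _eer_from_curve(fpr, tpr)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, eer=eer)


def _eer_from_curve(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Crossing of FPR and FNR along the ROC polyline, linearly interpolated."""
    fnr = 1.0 - tpr
    diff = fpr - fnr  # monotone non-decreasing along the curve
    idx = int(np.searchsorted(diff >= 0, True))
    if idx == 0:
        return float(fpr[0])
    f1, f2 = fpr[idx - 1], fpr[idx]
    g1, g2 = fnr[idx - 1], fnr[idx]
    denom = (f2 - f1) - (g2 - g1)
    if denom == 0:
        return float((f1 + g1) / 2.0)
    t = (g1 - f1) / denom
    return float(f1 + t * (f2 - f1))


def equal_error_rate(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rate at the threshold where false-positive and false-negative rates
    coincide, interpolating between bracketing ROC points."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return _eer_from_curve(fpr, tpr)


def history_ablation(
    states_dataset: Sequence[tuple[Sequence, np.ndarray]],
    model_names: Sequence[str],
    history_lengths: Sequence[int],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Grouped-CV AUC/EER for every (model, history length) pair.

    ``states_dataset`` is a sequence of per-video (states_by_frame, labels);
    features are rebuilt at each history length so every cell of the table is
    computed under identical conditions.
    """
    from .features import video_feature_matrix

    if not history_lengths:
        raise ValueError("history_lengths must be non-empty")
    rows = []
    for h in history_lengths:
        dataset = [
            (video_feature_matrix(states, h), np.asarray(labels, dtype=int))
            for states, labels in states_dataset
        ]
        for model_name in model_names:
            scores, labels, _ = grouped_cv_scores(dataset, model_name, config)
            curve = roc_auc(scores, labels)
            rows.append(
                {"model": model_name, "history": h, "auc": curve.auc, "eer": curve.eer}
            )
    return pd.DataFrame(rows, columns=["model", "history", "auc", "eer"])
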