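"""Classifier harness and ROC/AUC/EER metrics against brute-force oracles."""

import logging

import numpy as np
import pytest

from oracles import pairwise_auc, sweep_eer
from pipettewatch.config import PipelineConfig
from pipettewatch.predict import (
    MODEL_NAMES,
    equal_error_rate,
    fit_classifier,
    grouped_cv_scores,
    history_ablation,
    roc_auc,
    score_anomaly,
)

CONFIG = PipelineConfig(seed=0)


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    # non-negative, and separated in feature *ratios* so that count-based
    # models (multinomial_nb) separate it as easily as geometric ones
    X0 = rng.uniform(0.0, 0.5, size=(n, 4))
    X0[:, 0] += rng.uniform(4.0, 5.0, size=n)
    X1 = rng.uniform(0.0, 0.5, size=(n, 4))
    X1[:, 1] += rng.uniform(4.0, 5.0, size=n)
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestRocMetrics:
    def test_auc_hand_example(self):
        curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == 1.0
        assert curve.eer == 0.0

    def test_all_ties_is_chance(self):
        curve = roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(0.5)
        assert curve.eer == pytest.approx(0.5)

    def test_eer_interleaved_example(self):
        # enumerated: at threshold 0.5 one of two negatives and one of two
        # positives are misclassified, so FPR = FNR = 0.5
        assert equal_error_rate([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_eer_anti_ordered_is_one(self):
        assert equal_error_rate([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            equal_error_rate([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert curve.eer == pytest.approx(sweep_eer(list(scores), list(labels)),
                                          abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0.01, 0.99, 30))  # tie-free
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]  # both classes
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0)


class TestFitClassifier:
    @pytest.mark.parametrize("model_name", MODEL_NAMES)
    def test_separable_training_auc_is_one(self, model_name):
        X, y = separable_toy()
        model = fit_classifier(X, y, model_name, seed=0)
        scores = score_anomaly(model, X)
        assert roc_auc(scores, y).auc == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            fit_classifier(X, np.zeros(5, dtype=int), "svc")

    def test_multinomial_rejects_negative_features(self):
        X, y = separable_toy()
        X[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fit_classifier(X, y, "multinomial_nb")

    def test_deterministic_given_seed(self):
        X, y = separable_toy(seed=3)
        s1 = score_anomaly(fit_classifier(X, y, "svc", seed=7), X)
        s2 = score_anomaly(fit_classifier(X, y, "svc", seed=7), X)
        assert np.array_equal(s1, s2)


def toy_videos(n_videos=4, frames=25, seed=0):
    """Per-video feature matrices: anomalous videos shifted in mean."""
    rng = np.random.default_rng(seed)
    dataset = []
    for v in range(n_videos):
        anomalous = v % 2 == 1
        X = rng.normal(3.0 if anomalous else 0.0, 1.0, size=(frames, 6))
        y = np.full(frames, int(anomalous))
        dataset.append((X, y))
    return dataset


class TestGroupedCv:
    def test_every_frame_scored_exactly_once(self):
        dataset = toy_videos()
        scores, labels, groups = grouped_cv_scores(dataset, "logistic_regression", CONFIG)
        assert len(scores) == sum(len(y) for _, y in dataset)
        counts = np.bincount(groups)
        assert all(counts[v] == len(dataset[v][1]) for v in range(len(dataset)))

    def test_single_video_rejected(self):
        with pytest.raises(ValueError):
            grouped_cv_scores(toy_videos(1), "svc", CONFIG)

    def test_single_class_dataset_rejected(self):
        dataset = [(np.zeros((5, 2)), np.zeros(5, dtype=int))] * 3
        with pytest.raises(ValueError):
            grouped_cv_scores(dataset, "svc", CONFIG)

    def test_one_class_training_fold_skipped_with_warning(self, caplog):
        # two videos, one per class: every training fold is single-class
        dataset = toy_videos(2)
        with caplog.at_level(logging.WARNING):
            with pytest.raises(ValueError):
                # nothing remains to pool, so concatenate fails loudly
                grouped_cv_scores(dataset, "logistic_regression", CONFIG)
        assert any("one class" in r.message for r in caplog.records)

    def test_deterministic_rerun(self):
        dataset = toy_videos(seed=5)
        s1, _, _ = grouped_cv_scores(dataset, "svc", CONFIG)
        s2, _, _ = grouped_cv_scores(dataset, "svc", CONFIG)
        assert np.array_equal(s1, s2)


class TestHistoryAblation:
    def states_dataset(self, n_videos=4, frames=20):
        from pipettewatch.features import frame_states, PipetteGeometry
        from pipettewatch.selfcomp import ContourBox
        from pipettewatch.video import Box

        geo = PipetteGeometry(roi_box=Box(0, 0, 16, 20), n_pipettes=2)
        out = []
        for v in range(n_videos):
            anomalous = v % 2 == 1
            states = []
            for t in range(frames):
                h = 4 if anomalous else 14
                slots = [ContourBox(box=Box(0, 0, 6, h), area=6 * h),
                         ContourBox(box=Box(8, 0, 6, h), area=6 * h)]
                states.append(frame_states(slots, geo, t))
            out.append((states, np.full(frames, int(anomalous))))
        return out

    def test_table_shape_and_determinism(self):
        cfg = PipelineConfig(n_pipettes=2)
        ds = self.states_dataset()
        t1 = history_ablation(ds, ["logistic_regression", "gaussian_nb"], [0, 2], cfg)
        assert list(t1.columns) == ["model", "history", "auc", "eer"]
        assert len(t1) == 4
        t2 = history_ablation(ds, ["logistic_regression", "gaussian_nb"], [0, 2], cfg)
        assert t1.equals(t2)

    def test_empty_history_list_rejected(self):
        with pytest.raises(ValueError):
            history_ablation(self.states_dataset(), ["svc"], [], CONFIG)
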