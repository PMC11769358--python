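"""Classifier structure, metrics arithmetic, splits, selection and voting."""

import numpy as np
import pytest

from eegtranslate.ied_classifier import (
    ClassifierConfig,
    CrossValidationPlan,
    EEGNetClassifier,
    average_vote,
    classification_metrics,
    inter_subject_eval,
    predict_proba,
    select_training_subjects,
    stratified_split,
    train_classifier,
)

RNG = np.random.default_rng(21)


def toy_data(n=60, L=64, M=4, seed=0):
    """Linearly separable toy segments: spike at sample 32 vs flat background."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(0, 0.05, (n, L, M))
    spike = np.exp(-0.5 * ((np.arange(L) - 32) / 2.5) ** 2)
    X[y == 1] += 0.5 * spike[:, None]
    return np.clip(X, -1, 1), y


FAST = ClassifierConfig(epochs=25, seed=0)


class TestClassifier:
    def test_separable_task_high_accuracy(self):
        """On spike-vs-flat toy data the classifier reaches >=95% training
        accuracy in a majority of 3 seeds."""
        X, y = toy_data()
        wins = 0
        for seed in range(3):
            clf = train_classifier(X, y, ClassifierConfig(epochs=25, seed=seed))
            acc = np.mean((predict_proba(clf, X) >= 0.5) == y)
            wins += acc >= 0.95
        assert wins >= 2

    def test_structure_no_normalization_only_max_pooling(self):
        clf = EEGNetClassifier(64, 4, FAST, np.random.default_rng(0))
        kinds = clf.layer_kinds
        assert not any("norm" in k for k in kinds)
        assert "maxpool" in kinds and not any("avgpool" in k for k in kinds)

    def test_seed_determinism(self):
        X, y = toy_data(n=20)
        p1 = predict_proba(train_classifier(X, y, FAST), X)
        p2 = predict_proba(train_classifier(X, y, FAST), X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X, y = toy_data(n=10)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(X, np.ones_like(y), FAST)

    def test_predict_proba_contract(self):
        X, y = toy_data(n=12)
        clf = train_classifier(X, y, FAST)
        p = predict_proba(clf, X)
        assert p.shape == (12,) and np.all((p >= 0) & (p <= 1))
        # duplicated segment gives identical probability; order is preserved
        p2 = predict_proba(clf, np.stack([X[3], X[3], X[5]]))
        assert p2[0] == p2[1] == pytest.approx(p[3])
        assert p2[2] == pytest.approx(p[5])


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0])
        m = classification_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.ACC, m.SEN, m.SPC, m.PRC, m.F1, m.AUC) == (1, 1, 1, 1, 1, 1)

    def test_hand_confusion_matrix(self):
        # TP=3, FN=1, TN=2, FP=2 -> SEN=0.75, SPC=0.5, ACC=0.625
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.55, 0.3, 0.1])
        m = classification_metrics(y, p)
        assert m.confusion == {"TP": 3, "FN": 1, "TN": 2, "FP": 2}
        assert m.SEN == 0.75 and m.SPC == 0.5 and m.ACC == 0.625

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 2000)
        p = rng.random(2000)
        m = classification_metrics(y, p)
        assert abs(m.AUC - 0.5) < 0.05

    def test_auc_matches_sklearn_and_monotone_invariance(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 300)
        p = rng.random(300)
        m = classification_metrics(y, p)
        assert m.AUC == pytest.approx(roc_auc_score(y, p), abs=1e-10)
        m2 = classification_metrics(y, 1 / (1 + np.exp(-5 * (p - 0.5))))
        assert m2.AUC == pytest.approx(m.AUC, abs=1e-10)

    def test_acc_is_prevalence_weighted_combination(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        m = classification_metrics(y, p)
        prev = y.mean()
        assert m.ACC == pytest.approx(prev * m.SEN + (1 - prev) * m.SPC)

    def test_single_class_reported_as_nan(self):
        m = classification_metrics(np.ones(5, dtype=int), np.full(5, 0.9))
        assert m.SEN == 1.0 and np.isnan(m.SPC) and np.isnan(m.AUC)


class TestSplitsAndSelection:
    def test_70_10_20_sizes(self):
        y = np.array([0, 1] * 50)
        tr, va, te = stratified_split(y, CrossValidationPlan(), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_stratification_within_one_segment(self):
        y = np.array([0, 1] * 25)
        tr, va, te = stratified_split(y, CrossValidationPlan(), seed=1)
        for idx in (tr, va, te):
            counts = np.bincount(y[idx], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_split_determinism_and_disjointness(self):
        y = np.array([0, 1] * 20)
        a = stratified_split(y, CrossValidationPlan(), seed=3)
        b = stratified_split(y, CrossValidationPlan(), seed=3)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
        allidx = np.concatenate(a)
        assert len(np.unique(allidx)) == len(y)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CrossValidationPlan(train_fraction=0.8)

    def test_selection_strict_inequality(self):
        accs = {"A": 0.80, "B": 0.70, "C": 0.71}
        assert select_training_subjects(accs) == ["A", "C"]
        assert select_training_subjects({"A": 0.5, "B": 0.6}) == []
        assert select_training_subjects({"A": 0.9, "B": 0.99}) == ["A", "B"]
        with pytest.raises(ValueError):
            select_training_subjects({})


class TestVoting:
    def test_average_vote_matches_loop(self):
        rng = np.random.default_rng(6)
        probs = rng.random((4, 9))
        expected = [sum(probs[m][i] for m in range(4)) / 4 for i in range(9)]
        np.testing.assert_allclose(average_vote(probs), expected)

    def test_tie_rule_half_counts_as_ied(self):
        m = classification_metrics(np.array([1, 0]), np.array([0.5, 0.5]))
        assert m.confusion["TP"] == 1 and m.confusion["FP"] == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        probs = rng.random((5, 8))
        np.testing.assert_allclose(average_vote(probs), average_vote(probs[::-1]))

    def test_n_equals_one_reduces_to_single_model(self):
        """Inter-subject ensemble of size 1 equals that classifier's metrics."""
        from eegtranslate.networks import ArchitectureConfig
        from eegtranslate.synthetic import (SimulationConfig, default_forward_model,
                                            simulate_subject)
        from eegtranslate.trainer import build_model

        cfg = SimulationConfig(n_subjects=1, segments_per_subject=24, M=8, M_bar=4,
                               snr_db=15.0, target_visible_fraction=None)
        fwd = default_forward_model(cfg, np.random.default_rng(0), attenuation=1.0,
                                    attenuation_spread=0.0)
        train_rec = simulate_subject(cfg, fwd, subject_seed=1, subject_id="A")
        test_rec = simulate_subject(cfg, fwd, subject_seed=2, subject_id="B")
        model = build_model(ArchitectureConfig.tiny(), seed=0)  # untrained mapping
        from eegtranslate.trainer import translate

        Xtr = np.stack([s.scalp.samples for s in train_rec.segments])
        ytr = np.array([1 if s.label == "IED" else 0 for s in train_rec.segments])
        clf = train_classifier(translate(model, Xtr), ytr, FAST)
        m_ens = inter_subject_eval(test_rec.segments, {"A": (model, clf)})
        Xte = np.stack([s.scalp.samples for s in test_rec.segments])
        yte = np.array([1 if s.label == "IED" else 0 for s in test_rec.segments])
        m_single = classification_metrics(yte, predict_proba(clf, translate(model, Xte)))
        assert m_ens.ACC == m_single.ACC and m_ens.confusion == m_single.confusion

    def test_test_subject_overlap_rejected(self):
        from eegtranslate.networks import ArchitectureConfig
        from eegtranslate.trainer import build_model
        from eegtranslate.segment_store import (IntracranialSegment, PairedSegment,
                                                ScalpSegment)

        seg = PairedSegment(ScalpSegment(np.zeros((64, 8))),
                            IntracranialSegment(np.zeros((64, 4))),
                            label="IED", subject_id="A")
        model = build_model(ArchitectureConfig.tiny(), seed=0)
        with pytest.raises(ValueError, match="overlap"):
            inter_subject_eval([seg], {"A": (model, None)})
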