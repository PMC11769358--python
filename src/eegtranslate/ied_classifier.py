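"""IED / non-IED classification of (estimated) intracranial segments, with the
intra-subject and inter-subject evaluation protocols.

The classifier is a compact convolutional network in the EEGNet family —
temporal convolution, depthwise spatial convolution across all sensors,
separable (depthwise temporal + pointwise) convolution, dense sigmoid output
— with two deliberate modifications: **no normalization layers** and **max
pooling instead of average pooling**.

Protocols:

* *intra-subject*: a subject's scalp segments are mapped to estimated
  intracranial segments (deterministic mean-latent translation); the
  classifier is trained on a stratified 70% split, selected on 10%
  validation, and scored on the remaining 20%.
* *inter-subject*: for a held-out subject, every selected training subject n
  (those with intra-subject accuracy strictly above 70%) contributes a vote:
  the test scalp data is mapped through subject n's translation model and
  scored by subject n's classifier; the N probability vectors are averaged
  (average voting) and thresholded at 0.5 (>= 0.5 counts as IED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor
from ._modules import ConvTime, Dense, Module
from .trainer import TranslationModel, translate

__all__ = [
    "ClassifierConfig",
    "ClassificationMetrics",
    "CrossValidationPlan",
    "EEGNetClassifier",
    "train_classifier",
    "predict_proba",
    "classification_metrics",
    "stratified_split",
    "intra_subject_eval",
    "select_training_subjects",
    "inter_subject_eval",
    "average_vote",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Compact convolutional classifier hyperparameters.

    Pooling is always max and there are no normalization layers (the two
    modifications relative to the stock EEGNet design); both are structural
    and not configurable.
    """

    temporal_kernel_len: int = 17
    n_temporal_filters: int = 8
    depth_multiplier: int = 2
    separable_kernel_len: int = 9
    pool1: int = 4
    pool2: int = 4
    dropout_rate: float = 0.25
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class ClassificationMetrics:
    ACC: float
    SEN: float
    SPC: float
    PRC: float
    F1: float
    AUC: float
    roc_points: list = field(default_factory=list)
    confusion: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CrossValidationPlan:
    """Split fractions and subject-selection rule of the two protocols."""

    mode: str = "intra"                      # 'intra' or 'inter'
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20
    selection_threshold: float = 0.70        # intra-ACC cutoff (strict >)
    n_training_subjects: int | None = None   # N, set after selection

    def __post_init__(self):
        if self.mode not in ("intra", "inter"):
            raise ValueError("mode must be 'intra' or 'inter'")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, expected 1")
        if self.mode == "inter" and self.n_training_subjects is not None \
                and self.n_training_subjects < 1:
            raise ValueError("inter mode requires N >= 1")


class EEGNetClassifier(Module):
    """(L, Mbar) segment -> IED probability."""

    def __init__(self, L: int, n_sensors: int, cfg: ClassifierConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        f1, d = cfg.n_temporal_filters, cfg.depth_multiplier
        f2 = f1 * d
        self.conv_temporal = ConvTime(1, f1, cfg.temporal_kernel_len, rng)
        from ._modules import _param, _zeros

        self.w_spatial = _param(rng, (f1, d, n_sensors), n_sensors, d)
        self.b_spatial = _zeros((f2,))
        self.w_sep_depth = _param(rng, (f2, cfg.separable_kernel_len),
                                  cfg.separable_kernel_len, 1)
        self.b_sep_depth = _zeros((f2,))
        self.conv_pointwise = ConvTime(f2, f2, 1, rng)
        L_out = L // (cfg.pool1 * cfg.pool2)
        self.head = Dense(f2 * L_out, 1, rng)
        self.L, self.n_sensors = L, n_sensors

    #: layer sequence for introspection; contains no normalization layers and
    #: only max pooling
    @property
    def layer_kinds(self) -> list[str]:
        return ["conv_temporal", "depthwise_spatial", "elu", "maxpool", "dropout",
                "depthwise_temporal", "conv_pointwise", "elu", "maxpool", "dropout",
                "dense", "sigmoid"]

    def __call__(self, x, rng: np.random.Generator | None = None) -> Tensor:
        """x: (B, L, Mbar) array or Tensor; rng enables dropout (training)."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))
        if t.ndim != 3 or t.shape[1:] != (self.L, self.n_sensors):
            raise ValueError(
                f"classifier expects (batch, {self.L}, {self.n_sensors}), got {t.shape}"
            )
        b = t.shape[0]
        h = t.reshape(b, 1, self.L, self.n_sensors)
        h = self.conv_temporal(h)
        h = h.depthwise_spatial(self.w_spatial, self.b_spatial)
        h = h.elu().maxpool_time(self.cfg.pool1).dropout(self.cfg.dropout_rate, rng)
        h = h.depthwise_conv_time(self.w_sep_depth, self.b_sep_depth)
        h = self.conv_pointwise(h)
        h = h.elu().maxpool_time(self.cfg.pool2).dropout(self.cfg.dropout_rate, rng)
        return self.head(h.reshape(b, -1)).sigmoid().reshape(b)


def _as_xy(segments, labels):
    X = np.asarray(segments, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 3 or len(X) != len(y):
        raise ValueError("segments must be (n, L, Mbar) with one label each")
    return X, y


def train_classifier(segments, labels, cfg: ClassifierConfig,
                     val_segments=None, val_labels=None) -> EEGNetClassifier:
    """Train with binary cross entropy; if a validation set is given, the
    parameters with the best validation accuracy are kept."""
    X, y = _as_xy(segments, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    ss = np.random.SeedSequence(cfg.seed)
    init_seq, train_seq = ss.spawn(2)
    model = EEGNetClassifier(X.shape[1], X.shape[2], cfg, np.random.default_rng(init_seq))
    rng = np.random.default_rng(train_seq)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=(0.9, 0.999))
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            p = model(X[idx], rng=rng)
            t = Tensor(y[idx].astype(float))
            eps = 1e-7
            p_c = p * (1 - 2 * eps) + eps
            loss = -(t * p_c.log() + (1.0 - t) * (1.0 - p_c).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        if val_segments is not None:
            acc = float(np.mean((predict_proba(model, val_segments) >= 0.5)
                                == np.asarray(val_labels)))
            if acc > best_acc:
                best_acc, best_state = acc, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def predict_proba(model: EEGNetClassifier, segments) -> np.ndarray:
    """IED probability per segment, in input order (dropout disabled)."""
    X = np.asarray(segments, dtype=float)
    single = X.ndim == 2
    out = model(X[None] if single else X, rng=None).data
    return out[0] if single else out


def average_vote(probability_vectors) -> np.ndarray:
    """Elementwise mean of the ensemble members' probability vectors."""
    arr = np.asarray(probability_vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected (n_models, n_segments)")
    return arr.mean(axis=0)


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(labels, probabilities, threshold: float = 0.5
                           ) -> ClassificationMetrics:
    """Confusion-matrix metrics plus a threshold-sweep ROC curve.

    The IED class (label 1) is positive.  Predictions use ``probability >=
    threshold``.  With a single-class ground truth the undefined entries (SEN
    or SPC, and AUC) are reported as NaN rather than silently zero.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and probabilities must be equal-length vectors")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    sen = tp / n_pos if n_pos else float("nan")
    spc = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / len(y)
    prc = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (2 * prc * sen / (prc + sen)) if (tp + fp) and n_pos and (prc + sen) > 0 \
        else float("nan")

    if n_pos and n_neg:
        order = np.argsort(-p, kind="stable")
        thresholds = np.concatenate([[np.inf], np.unique(p)[::-1]])
        roc = []
        for th in thresholds:
            hit = p >= th
            roc.append((np.sum(hit & (y == 0)) / n_neg, np.sum(hit & (y == 1)) / n_pos))
        roc = sorted(set(roc))
        fpr = np.array([r[0] for r in roc])
        tpr = np.array([r[1] for r in roc])
        auc = float(np.trapezoid(tpr, fpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        auc, roc_points = float("nan"), []
    return ClassificationMetrics(ACC=acc, SEN=sen, SPC=spc, PRC=prc, F1=f1, AUC=auc,
                                 roc_points=roc_points,
                                 confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp})


# ---------------------------------------------------------------------------
# protocols


def stratified_split(labels, plan: CrossValidationPlan, seed: int = 0):
    """Seeded stratified (train, val, test) index split preserving the label
    ratio within +-1 segment per split."""
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_test = int(round(plan.test_fraction * n))
        n_val = int(round(plan.val_fraction * n))
        test_idx.extend(idx[:n_test])
        val_idx.extend(idx[n_test:n_test + n_val])
        train_idx.extend(idx[n_test + n_val:])
    if not test_idx or not train_idx:
        raise ValueError(
            f"cohort too small for a {plan.train_fraction}/{plan.val_fraction}/"
            f"{plan.test_fraction} split; provide more segments"
        )
    return (np.sort(np.array(train_idx)), np.sort(np.array(val_idx)),
            np.sort(np.array(test_idx)))


def _segments_to_arrays(segments):
    X = np.stack([s.scalp.samples for s in segments])
    y = np.array([1 if s.label == "IED" else 0 for s in segments], dtype=int)
    return X, y


def intra_subject_eval(segments, mapping_model: TranslationModel,
                       plan: CrossValidationPlan, cfg: ClassifierConfig,
                       return_classifier: bool = False):
    """70/10/20 protocol on one subject's estimated intracranial segments.

    The subject's scalp segments are mapped through the translation model
    (deterministic mean-latent mode); the classifier is trained on the train
    split, checkpoint-selected on validation accuracy and scored on test.
    """
    X_scalp, y = _segments_to_arrays(segments)
    X_est = translate(mapping_model, X_scalp, mode="mean")
    tr, va, te = stratified_split(y, plan, seed=cfg.seed)
    clf = train_classifier(X_est[tr], y[tr], cfg,
                           val_segments=X_est[va] if len(va) else None,
                           val_labels=y[va] if len(va) else None)
    metrics = classification_metrics(y[te], predict_proba(clf, X_est[te]))
    if return_classifier:
        return metrics, clf
    return metrics


def select_training_subjects(intra_results: dict, threshold: float = 0.70) -> list:
    """Subjects whose intra-subject accuracy is strictly above the threshold,
    sorted by subject id."""
    if not intra_results:
        raise ValueError("empty intra-subject result map")
    return sorted(sid for sid, acc in intra_results.items() if acc > threshold)


def inter_subject_eval(test_segments, ensemble: dict) -> ClassificationMetrics:
    """Leave-one-subject-out ensemble scoring with average voting.

    ``ensemble`` maps each selected training subject id to its
    ``(TranslationModel, EEGNetClassifier)`` pair.  The held-out subject's
    scalp segments are mapped through *each* subject's translation model and
    scored by that subject's classifier; probabilities are averaged and
    thresholded at 0.5 (>= 0.5 counts as IED).
    """
    if not ensemble:
        raise ValueError("inter-subject evaluation needs N >= 1 selected subjects")
    X_scalp, y = _segments_to_arrays(test_segments)
    test_ids = {s.subject_id for s in test_segments}
    overlap = test_ids & set(ensemble)
    if overlap:
        raise ValueError(f"test subject {sorted(overlap)} overlaps the training ensemble")
    probs = []
    for sid in sorted(ensemble):
        mapping_model, clf = ensemble[sid]
        X_est = translate(mapping_model, X_scalp, mode="mean")
        probs.append(predict_proba(clf, X_est))
    return classification_metrics(y, average_vote(probs))
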