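"""Confusion-matrix metrics and cross-validation of the PCA-discriminant chain.

The positive class is *tumor* throughout: sensitivity is the true-positive
rate among tumor samples, specificity the true-negative rate among normals.

Cross-validation refits the dimension-reduction (PCA per modality) inside
every training fold by default, so the held-out sample never influences the
projection.  ``paper_mode`` instead fits PCA once on all samples and
cross-validates only the classifier — the leakage-prone but historically
common chemometrics protocol — so both protocols can be reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import FoldError, InvalidSpecError, UndefinedMetricError
from .models import (
    FeatureMatrix,
    fit_discriminant,
    fit_pca,
    predict_discriminant,
    transform_pca,
    fuse_features,
)

__all__ = [
    "ConfusionMatrix",
    "PerformanceMetrics",
    "CvConfig",
    "CvResult",
    "confusion",
    "performance",
    "loocv_folds",
    "stratified_kfold_folds",
    "cross_validate",
    "loocv",
    "kfold_cv",
    "resubstitution",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts under an explicit positive-class convention."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "tumor"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidSpecError("confusion counts must be non-negative")
        if self.total == 0:
            raise InvalidSpecError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "positive_class": self.positive_class,
        }


class PerformanceMetrics(NamedTuple):
    """Percentages: accuracy, sensitivity (TPR), specificity (TNR), error rate."""

    accuracy: float
    sensitivity: float
    specificity: float
    error_rate: float


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_class: str = "tumor"
) -> ConfusionMatrix:
    """Standard 2x2 counts; raises if more than two classes are present."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidSpecError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if classes.size > 2:
        raise InvalidSpecError(f"binary confusion requires <= 2 classes, got {classes.tolist()}")
    pos_true = y_true == positive_class
    pos_pred = y_pred == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
        positive_class=positive_class,
    )


def performance(cm: ConfusionMatrix) -> PerformanceMetrics:
    """accuracy, sensitivity, specificity and error rate, all in percent."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive-class samples")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative-class samples")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return PerformanceMetrics(
        accuracy=accuracy,
        sensitivity=100.0 * cm.tp / (cm.tp + cm.fn),
        specificity=100.0 * cm.tn / (cm.tn + cm.fp),
        error_rate=100.0 - accuracy,
    )


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def loocv_folds(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """n folds of test size 1."""
    idx = np.arange(n)
    return [(np.delete(idx, i), np.asarray([i])) for i in range(n)]


def stratified_kfold_folds(
    labels: Sequence, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition into k disjoint, exhaustive folds.

    Each class's shuffled indices are dealt as evenly as possible; the extra
    samples rotate across folds between classes so overall fold sizes differ
    by at most one.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 2 <= k <= n:
        raise InvalidSpecError(f"k must satisfy 2 <= k <= n (= {n}), got {k}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    extra_ptr = 0  # rotates which folds receive remainders, across classes
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        base, rem = divmod(idx.size, k)
        counts = np.full(k, base)
        for _ in range(rem):
            counts[extra_ptr % k] += 1
            extra_ptr += 1
        start = 0
        for f in range(k):
            assignment[idx[start : start + counts[f]]] = f
            start += counts[f]
    folds = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[assignment == f]
        if test.size == 0:
            raise FoldError(f"fold {f} received no samples; reduce k")
        folds.append((all_idx[assignment != f], test))
    return folds


# ---------------------------------------------------------------------------
# Cross-validation of the PCA -> (fusion) -> discriminant chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvConfig:
    """How each fold refits the chain.

    classifier: 'linear' or 'quadratic'.
    n_components: principal components per modality (capped by what the
        training fold supports).
    paper_mode: fit PCA once on the full dataset, cross-validate only the
        classifier.
    group_by_patient: keep each patient's tumor+normal pair in one fold.
    """

    classifier: str = "linear"
    n_components: int = 2
    ridge: float | None = None
    paper_mode: bool = False
    group_by_patient: bool = False


@dataclass
class CvResult:
    """Outcome of one cross-validation run."""

    scheme: str
    k: int | None
    seed: int | None
    per_fold_errors: np.ndarray
    error_rate: float
    y_true: np.ndarray = field(default=None, repr=False)
    y_pred: np.ndarray = field(default=None, repr=False)

    @property
    def accuracy(self) -> float:
        return 100.0 - self.error_rate


def _as_modalities(dataset) -> list[FeatureMatrix]:
    if isinstance(dataset, FeatureMatrix):
        return [dataset]
    mods = list(dataset)
    if not mods or not all(isinstance(m, FeatureMatrix) for m in mods):
        raise InvalidSpecError("dataset must be a FeatureMatrix or a sequence of them")
    ref = mods[0]
    for m in mods[1:]:
        if m.sample_ids != ref.sample_ids or not np.array_equal(m.labels, ref.labels):
            raise InvalidSpecError("modalities must share sample ids and labels (align first)")
    return mods


def _fold_scores(
    mods: list[FeatureMatrix],
    train: np.ndarray,
    test: np.ndarray,
    cfg: CvConfig,
    full_models=None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    train_parts, test_parts = [], []
    for mi, m in enumerate(mods):
        if full_models is not None:
            model = full_models[mi]
            scores_tr = transform_pca(model, m.subset(train))
            scores_te = transform_pca(model, m.subset(test))
        else:
            m_tr = m.subset(train)
            k = min(cfg.n_components, m_tr.n_samples - 1, m_tr.n_features)
            model = fit_pca(m_tr, k)
            scores_tr = transform_pca(model, m_tr)
            scores_te = transform_pca(model, m.subset(test))
        train_parts.append(scores_tr)
        test_parts.append(scores_te)
    if len(mods) == 1:
        return train_parts[0], test_parts[0]
    fused_tr, fused_te = train_parts[0], test_parts[0]
    for nxt_tr, nxt_te in zip(train_parts[1:], test_parts[1:]):
        fused_tr = fuse_features(fused_tr, nxt_tr)
        fused_te = fuse_features(fused_te, nxt_te)
    return fused_tr, fused_te


def cross_validate(
    dataset,
    folds: list[tuple[np.ndarray, np.ndarray]],
    cfg: CvConfig = CvConfig(),
    *,
    scheme: str = "custom",
    k: int | None = None,
    seed: int | None = None,
) -> CvResult:
    """Run the configured chain over explicit folds.

    ``dataset`` is one FeatureMatrix (single modality) or a sequence of them
    (per-modality PCA scores are fused inside each fold).
    """
    mods = _as_modalities(dataset)
    labels = mods[0].labels
    n = labels.size
    covered = np.sort(np.concatenate([t for _, t in folds]))
    if not np.array_equal(covered, np.arange(n)):
        raise FoldError("test folds must partition the samples exactly")

    full_models = None
    if cfg.paper_mode:
        full_models = [
            fit_pca(m, min(cfg.n_components, m.n_samples - 1, m.n_features)) for m in mods
        ]

    y_pred = np.empty(n, dtype=labels.dtype)
    per_fold = []
    for train, test in folds:
        tr_classes = np.unique(labels[train])
        if tr_classes.size < 2:
            raise FoldError(
                f"training fold lost a class (only {tr_classes.tolist()} present)"
            )
        tr_fm, te_fm = _fold_scores(mods, train, test, cfg, full_models)
        clf = fit_discriminant(tr_fm, kind=cfg.classifier, ridge=cfg.ridge)
        pred = predict_discriminant(clf, te_fm)
        y_pred[test] = pred
        per_fold.append(float(np.mean(pred != labels[test])))
    error_rate = 100.0 * float(np.mean(y_pred != labels))
    return CvResult(
        scheme=scheme,
        k=k,
        seed=seed,
        per_fold_errors=np.asarray(per_fold),
        error_rate=error_rate,
        y_true=labels.copy(),
        y_pred=y_pred,
    )


def _patient_of(sample_id: str) -> str:
    return sample_id.split(":", 1)[0]


def _grouped_loocv_folds(sample_ids: list[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    patients = sorted({_patient_of(s) for s in sample_ids})
    by_patient = {p: np.asarray([i for i, s in enumerate(sample_ids) if _patient_of(s) == p]) for p in patients}
    all_idx = np.arange(len(sample_ids))
    return [(np.setdiff1d(all_idx, by_patient[p]), by_patient[p]) for p in patients]


def loocv(dataset, cfg: CvConfig = CvConfig()) -> CvResult:
    """Leave-one-out cross-validation (leave-one-patient-out when grouped)."""
    mods = _as_modalities(dataset)
    n = mods[0].n_samples
    if n < 3:
        raise InvalidSpecError("LOOCV needs at least 3 samples")
    if np.unique(mods[0].labels).size < 2:
        raise InvalidSpecError("LOOCV needs both classes present")
    folds = (
        _grouped_loocv_folds(mods[0].sample_ids)
        if cfg.group_by_patient
        else loocv_folds(n)
    )
    return cross_validate(dataset, folds, cfg, scheme="loocv")


def kfold_cv(dataset, k: int = 10, seed: int = 0, cfg: CvConfig = CvConfig()) -> CvResult:
    """Seeded stratified k-fold cross-validation."""
    mods = _as_modalities(dataset)
    folds = stratified_kfold_folds(mods[0].labels, k, seed)
    return cross_validate(dataset, folds, cfg, scheme="kfold", k=k, seed=seed)


def resubstitution(dataset, cfg: CvConfig = CvConfig()) -> CvResult:
    """Train and evaluate on all samples (training/apparent error)."""
    mods = _as_modalities(dataset)
    n = mods[0].n_samples
    idx = np.arange(n)
    tr_fm, te_fm = _fold_scores(mods, idx, idx, cfg, None)
    clf = fit_discriminant(tr_fm, kind=cfg.classifier, ridge=cfg.ridge)
    pred = predict_discriminant(clf, te_fm)
    labels = mods[0].labels
    error_rate = 100.0 * float(np.mean(pred != labels))
    return CvResult(
        scheme="resubstitution",
        k=None,
        seed=None,
        per_fold_errors=np.asarray([error_rate / 100.0]),
        error_rate=error_rate,
        y_true=labels.copy(),
        y_pred=pred,
    )
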