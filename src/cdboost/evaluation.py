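"""PC/MC/FA confusion accounting, derived scores and stratified k-fold CV.

The confusion primitives partition the test set into percentages: PC
(perfect classification, correct predictions), MC (missed classification,
true class-1 records predicted class 0) and FA (false alarm, true class-0
records predicted class 1); PC + MC + FA = 100 by construction. The
derived scores are

    PI   = (PC - MC - FA) / PC * 100
    Sens = PC / (PC + FA) * 100
    Spec = PC / (PC + MC) * 100
    Acc  = (Sens + Spec) / 2
    GDR  = (PC - MC) / (PC + FA) * 100

Note these are NOT the usual TPR/TNR: they are ratios of the PC/MC/FA
percentages themselves, and are implemented exactly as defined above —
Accuracy is always the arithmetic mean of this Sensitivity and Specificity.
MSE compares the continuous classifier outputs with the encoded 0/1
targets. Cross-validation is stratified k-fold (default k=10, so 90% of
records train and 10% test per fold), with any feature selector refit
inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold

from .distance_features import encode_targets

__all__ = [
    "EvalReport",
    "confusion_rates",
    "performance_index",
    "sensitivity",
    "specificity",
    "accuracy",
    "gdr",
    "mse",
    "metrics_from_predictions",
    "kfold_cv",
]

METRIC_KEYS = ("PC", "MC", "FA", "PI", "Sensitivity", "Specificity", "Accuracy", "GDR", "MSE")


@dataclass
class EvalReport:
    """Per-fold metrics, their averages, fold assignments and the CV seed."""

    folds: list[dict]
    summary: dict
    fold_assignments: np.ndarray
    seed: int
    k: int
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "seed": self.seed,
            "folds": self.folds,
            "summary": self.summary,
            "fold_assignments": self.fold_assignments.tolist(),
        }


def confusion_rates(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> tuple[float, float, float]:
    """(PC, MC, FA) as percentages of the test set; they sum to 100."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    n = pred.size
    if n == 0:
        raise ValueError("empty input")
    if not (np.all(np.isin(pred, (0, 1))) and np.all(np.isin(true, (0, 1)))):
        raise ValueError("labels must be binary 0/1")
    pc = 100.0 * np.count_nonzero(pred == true) / n
    mc = 100.0 * np.count_nonzero((true == 1) & (pred == 0)) / n
    fa = 100.0 * np.count_nonzero((true == 0) & (pred == 1)) / n
    return pc, mc, fa


def performance_index(PC: float, MC: float, FA: float) -> float:
    """((PC - MC - FA) / PC) * 100; NaN (missing) when PC = 0."""
    if PC == 0:
        return float("nan")
    return (PC - MC - FA) / PC * 100.0


def sensitivity(PC: float, FA: float) -> float:
    """PC / (PC + FA) * 100."""
    return PC / (PC + FA) * 100.0


def specificity(PC: float, MC: float) -> float:
    """PC / (PC + MC) * 100."""
    return PC / (PC + MC) * 100.0


def accuracy(sens: float, spec: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    return (sens + spec) / 2.0


def gdr(PC: float, MC: float, FA: float) -> float:
    """Good detection rate: (PC - MC) / (PC + FA) * 100."""
    return (PC - MC) / (PC + FA) * 100.0


def mse(observed_outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared difference of continuous outputs from encoded targets."""
    o = np.asarray(observed_outputs, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if o.shape != t.shape:
        raise ValueError("length mismatch")
    if o.size == 0:
        raise ValueError("empty input")
    return float(np.mean((o - t) ** 2))


def metrics_from_predictions(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    outputs: np.ndarray | None = None,
) -> dict:
    """All nine scores from hard labels plus optional continuous outputs."""
    pc, mc, fa = confusion_rates(pred_labels, true_labels)
    sens = sensitivity(pc, fa)
    spec = specificity(pc, mc)
    vals = {
        "PC": pc,
        "MC": mc,
        "FA": fa,
        "PI": performance_index(pc, mc, fa),
        "Sensitivity": sens,
        "Specificity": spec,
        "Accuracy": accuracy(sens, spec),
        "GDR": gdr(pc, mc, fa),
    }
    if outputs is None:
        outputs = np.asarray(pred_labels, dtype=np.float64)
    vals["MSE"] = mse(outputs, encode_targets(true_labels))
    return vals


def kfold_cv(
    X,
    y: np.ndarray,
    model_factory,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    selector_factory=None,
    model_name: str = "",
) -> EvalReport:
    """Stratified k-fold cross-validation with fold-safe feature selection.

    ``X`` is either a plain feature matrix or any object a selector built by
    ``selector_factory`` can consume; in the latter case the selector is fit
    on each training fold only (never seeing test labels) and both folds are
    transformed through it. ``model_factory()`` must return a fresh model
    with ``fit``/``predict`` (and optionally ``predict_value``) per fold.
    """
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    if stratified and np.any(counts < k):
        raise ValueError(
            f"every class needs >= k={k} records (smallest has {counts.min()}); "
            "use a smaller k"
        )

    if selector_factory is None:
        X_mat = np.asarray(X, dtype=np.float64)

        def split_views(train_idx, test_idx):
            return X_mat[train_idx], X_mat[test_idx]

    else:

        def split_views(train_idx, test_idx):
            sel = selector_factory()
            sel.fit(_take(X, train_idx), y[train_idx])
            return sel.transform(_take(X, train_idx)), sel.transform(_take(X, test_idx))

    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(n, -1, dtype=np.int64)
    folds: list[dict] = []
    for fold_i, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        assignments[test_idx] = fold_i
        X_train, X_test = split_views(train_idx, test_idx)
        model = model_factory()
        model.fit(X_train, y[train_idx])
        pred = np.asarray(model.predict(X_test), dtype=np.int64)
        outputs = (
            np.asarray(model.predict_value(X_test), dtype=np.float64)
            if hasattr(model, "predict_value")
            else None
        )
        fold_metrics = metrics_from_predictions(pred, y[test_idx], outputs)
        fold_metrics["fold"] = fold_i
        fold_metrics["n_test"] = int(test_idx.size)
        folds.append(fold_metrics)

    summary = {
        key: float(np.nanmean([f[key] for f in folds])) for key in METRIC_KEYS
    }
    return EvalReport(
        folds=folds,
        summary=summary,
        fold_assignments=assignments,
        seed=seed,
        k=k,
        model=model_name,
    )


def _take(X, idx):
    """Index rows of a feature matrix or records of a CDFeatureMatrix."""
    from .correlation_dimension import CDFeatureMatrix

    if isinstance(X, CDFeatureMatrix):
        return CDFeatureMatrix(
            values=X.values[idx],
            n_channels=X.n_channels,
            n_windows=X.n_windows,
            config=X.config,
            labels=X.labels[idx] if X.labels is not None else None,
            subject_ids=[X.subject_ids[i] for i in idx] if X.subject_ids else [],
        )
    return np.asarray(X)[idx]
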