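"""Evaluation protocols and metrics.

The primary protocol is the jackknife (leave-one-out) test: each sample
in turn is held out, the model is trained on the remaining n-1 and
predicts the held-out sample.  The self-consistency (resubstitution) test
trains and predicts on the same samples.

Per class, sensitivity, specificity and the Matthews correlation
coefficient are computed on the one-vs-rest collapse of the confusion
matrix:

    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Overall accuracy is the fraction of correctly classified samples
(trace of the confusion matrix over n).  ROC curves are computed
one-vs-rest per class, interpolated onto a common false-positive-rate
grid and macro-averaged; the AUC is the trapezoidal area under the
averaged curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .classify import class_scores
from .denoise import WaveletSpec, denoise_matrix, denoise_rows_1d
from .fusion import FeatureMatrix

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_names) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(class_names)}
        k = len(class_names)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts=counts, class_names=list(class_names))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def ovr_collapse(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) of class i against the rest."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, fp, tn, fn


def binary_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 (with a warning) when the
    denominator vanishes."""
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / denom


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity/specificity/MCC per class (one-vs-rest) plus overall
    accuracy and the macro-averaged MCC."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, name in enumerate(cm.class_names):
        tp, fp, tn, fn = cm.ovr_collapse(i)
        sens = tp / (tp + fn) if (tp + fn) else 0.0
        spec = tn / (tn + fp) if (tn + fp) else 0.0
        per_class[name] = {
            "sens": sens, "spec": spec, "mcc": binary_mcc(tp, fp, tn, fn),
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        }
    oa = float(np.trace(cm.counts)) / cm.n
    macro_mcc = float(np.mean([v["mcc"] for v in per_class.values()]))
    return {"per_class": per_class, "oa": oa, "macro_mcc": macro_mcc}


@dataclass
class EvalReport:
    """Everything a protocol run produces."""

    confusion: ConfusionMatrix
    per_class: dict
    oa: float
    macro_mcc: float
    roc_points: np.ndarray  # (101, 2): FPR grid, averaged TPR
    auc: float
    protocol: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "oa": self.oa,
            "macro_mcc": self.macro_mcc,
            "auc": self.auc,
            "per_class": self.per_class,
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
            "roc_points": self.roc_points.tolist(),
            "params": self.params,
        }

    def summary(self) -> str:
        lines = [f"protocol: {self.protocol}"]
        lines.append(f"{'class':<16}{'Sens':>8}{'Spec':>8}{'MCC':>8}")
        for name, m in self.per_class.items():
            lines.append(
                f"{name:<16}{m['sens'] * 100:>7.2f}%{m['spec'] * 100:>7.2f}%"
                f"{m['mcc']:>8.3f}"
            )
        lines.append(f"OA: {self.oa * 100:.2f}%   macro-MCC: {self.macro_mcc:.3f}   "
                     f"AUC: {self.auc:.4f}")
        return "\n".join(lines)


def roc_ovr(y_true, scores: np.ndarray, class_names) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC per class, macro-averaged on a common FPR grid.

    Returns the averaged curve as a (101, 2) array of (FPR, TPR) and its
    trapezoidal AUC.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != len(class_names):
        raise ValueError("scores must have one column per class")
    tprs = []
    for i, name in enumerate(class_names):
        y_bin = (y_true == name).astype(int)
        col = scores[:, i]
        if y_bin.sum() == 0 or y_bin.sum() == len(y_bin) or np.ptp(col) == 0:
            warnings.warn(
                f"class {name!r}: degenerate scores or labels; using the "
                "chance diagonal", stacklevel=2,
            )
            tprs.append(FPR_GRID.copy())
            continue
        fpr, tpr, _ = roc_curve(y_bin, col)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    points = np.column_stack([FPR_GRID, mean_tpr])
    return points, auc


def _evaluate_predictions(y_true, y_pred, scores, class_names, protocol, params):
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, class_names)
    metrics = per_class_metrics(cm)
    roc_points, auc = roc_ovr(y_true, scores, class_names)
    return EvalReport(
        confusion=cm,
        per_class=metrics["per_class"],
        oa=metrics["oa"],
        macro_mcc=metrics["macro_mcc"],
        roc_points=roc_points,
        auc=auc,
        protocol=protocol,
        params=params,
    )


def self_consistency(X: FeatureMatrix, model) -> EvalReport:
    """Resubstitution test: train on all rows, predict the same rows."""
    class_names = sorted(set(X.labels))
    fitted = clone(model).fit(X.values, np.asarray(X.labels))
    y_pred = fitted.predict(X.values)
    scores = class_scores(fitted, X.values)
    return _evaluate_predictions(
        X.labels, y_pred, scores, class_names, "self_consistency", dict(X.params)
    )


def jackknife(
    X: FeatureMatrix,
    model,
    denoise_mode: str = "none",
    wavelet_spec: WaveletSpec | None = None,
) -> EvalReport:
    """Leave-one-out test with n folds.

    ``denoise_mode`` controls where wavelet denoising happens relative to
    the split:

    * ``"none"`` — X is used as given (pass an already-denoised matrix to
      replicate the whole-dataset protocol);
    * ``"paper_faithful"`` — X is 2-D denoised once, before the folds;
    * ``"leak_free"`` — each fold 2-D denoises its n-1 training rows and
      applies the train-derived global threshold to the held-out row in
      1-D.
    """
    n = X.n
    class_names = sorted(set(X.labels))
    if n < len(class_names) + 1:
        raise ValueError(f"need n >= k + 1 samples (n={n}, k={len(class_names)})")
    if denoise_mode not in ("none", "paper_faithful", "leak_free"):
        raise ValueError(f"unknown denoise_mode {denoise_mode!r}")
    if denoise_mode != "none" and wavelet_spec is None:
        wavelet_spec = WaveletSpec()
    if denoise_mode == "paper_faithful":
        X = denoise_matrix(X, wavelet_spec)

    labels = np.asarray(X.labels)
    k = len(class_names)
    y_pred = np.empty(n, dtype=object)
    scores = np.zeros((n, k))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train, y_train = X.values[mask], labels[mask]
        X_test = X.values[[i]]
        if denoise_mode == "leak_free":
            from .denoise import WaveletDenoiser

            den = WaveletDenoiser(**{
                "family": wavelet_spec.family, "level": wavelet_spec.level,
                "threshold_rule": wavelet_spec.threshold_rule,
                "threshold_mode": wavelet_spec.threshold_mode,
                "alpha": wavelet_spec.alpha, "extension": wavelet_spec.extension,
            })
            X_train = den.fit_transform(X_train)
            X_test = den.transform(X_test, leak_free=True)
        train_classes = set(y_train)
        if len(train_classes) < k:
            warnings.warn(
                f"fold {i}: class(es) {sorted(set(class_names) - train_classes)} "
                "absent from the training split", stacklevel=2,
            )
        fitted = clone(model).fit(X_train, y_train)
        y_pred[i] = fitted.predict(X_test)[0]
        fold_scores = class_scores(fitted, X_test)[0]
        fold_classes = list(fitted.classes_)
        for j, cls in enumerate(class_names):
            if cls in fold_classes:
                scores[i, j] = fold_scores[fold_classes.index(cls)]
    params = dict(X.params)
    params["denoise_mode"] = denoise_mode
    return _evaluate_predictions(
        labels, y_pred, scores, class_names, "jackknife", params
    )
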