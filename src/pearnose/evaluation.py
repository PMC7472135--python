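"""Confusion-matrix metrics and PCA reporting for grade classification.

Metrics are macro-averaged over the six browning grades: per-class
precision TP/(TP+FP) and recall TP/(TP+FN) are averaged unweighted, and
the headline macro-F1 is the *harmonic mean of the two macro averages*,
``2PR/(P+R)`` - not the mean of per-class F1 scores (that variant is also
reported, as ``macro_f1_per_class_mean``).  On a class-balanced evaluation
set accuracy equals macro-recall exactly, since every grade contributes
the same number of rows.

PCA is computed from the eigendecomposition of the covariance matrix of
the column-centred stable values (no rescaling by default; a
correlation-matrix option exists).  A component's contribution rate is its
eigenvalue as a percentage of total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import N_CLASSES
from .errors import DataValidationError


def harmonic_macro_f1(macro_precision: float, macro_recall: float) -> float:
    """2PR/(P+R); zero when both averages are zero."""
    p, r = float(macro_precision), float(macro_recall)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true grade, cols = predicted) and the
    derived accuracy / macro metrics, all in [0, 1]."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_f1_per_class_mean: float
    n_classes: int = N_CLASSES
    n_samples: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_f1_per_class_mean": self.macro_f1_per_class_mean,
        }

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy:.4f}  "
            f"macro-precision {self.macro_precision:.4f}  "
            f"macro-recall {self.macro_recall:.4f}  "
            f"macro-F1 {self.macro_f1:.4f}"
        )


def evaluate(true_labels, predicted_labels,
             n_classes: int = N_CLASSES) -> EvaluationReport:
    """Tally a confusion matrix and macro-averaged metrics.

    A grade that is never predicted has undefined precision; it is scored
    0 with a warning (likewise recall for a grade absent from the truth).
    """
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length; got "
            f"{y_true.shape} and {y_pred.shape}"
        )
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if len(v) and (v.min() < 0 or v.max() >= n_classes):
            raise DataValidationError(
                f"{name} labels outside 0..{n_classes - 1}"
            )
    n = len(y_true)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)

    tp = np.diag(confusion).astype(float)
    pred_pos = confusion.sum(axis=0).astype(float)
    true_pos = confusion.sum(axis=1).astype(float)
    if np.any(pred_pos == 0):
        warnings.warn(
            f"classes {np.flatnonzero(pred_pos == 0).tolist()} never "
            "predicted; their precision is reported as 0", RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1), 0.0)
        recall = np.where(true_pos > 0, tp / np.where(true_pos > 0, true_pos, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    return EvaluationReport(
        confusion=confusion,
        accuracy=float(tp.sum() / n) if n else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=harmonic_macro_f1(macro_p, macro_r),
        macro_f1_per_class_mean=float(f1.mean()),
        n_classes=n_classes,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Loadings (sensors x components, orthonormal columns), contribution
    rates in percent, and the projected scores."""

    loadings: np.ndarray
    contributions: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray


def pca_fit(X, n_components: int = 2, scale: str = "covariance") -> PCAResult:
    """Principal components via eigendecomposition of the covariance matrix.

    Columns are mean-centred (and additionally unit-scaled with
    ``scale="correlation"``); eigenvector signs are fixed by making each
    loading column's largest-magnitude entry positive.  ``contributions``
    holds the chosen components' explained-variance percentages; all
    eigenvalues (hence the full 100%) are available in ``eigenvalues``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    d = X.shape[1]
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in 1..{d}")
    if scale not in ("covariance", "correlation"):
        raise ValueError("scale must be 'covariance' or 'correlation'")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = Xc.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise DataValidationError("X has zero variance in every column")
    if scale == "correlation":
        if np.any(sd == 0):
            raise DataValidationError(
                "correlation-scaled PCA requires non-constant columns"
            )
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (len(X) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude entry of each loading is positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    total = eigvals.sum()
    contributions = 100.0 * eigvals[:n_components] / total
    loadings = eigvecs[:, :n_components]
    return PCAResult(
        loadings=loadings,
        contributions=contributions,
        scores=Xc @ loadings,
        eigenvalues=eigvals,
        mean=mean,
    )
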