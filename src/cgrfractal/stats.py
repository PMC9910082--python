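"""Downstream statistics: correlation sweeps, one-sided t-tests, LDA.

The correlation sweep asks, for every moment order q, how well D(q)
tracks each alpha-diversity index across a cohort of samples — richness
is expected to align with D(0), Shannon with D(1), Simpson with D(2) and
beyond. Group comparisons use Welch's unequal-variance t-test with the
one-sided "less" alternative. Classification uses Gaussian linear
discriminant analysis with class-proportion priors; the pooled
covariance is shrunk toward a scaled identity (Ledoit-Wolf) so the full
76-dimensional D(q) feature vector stays usable even with modest
per-class sample counts. Accuracy is reported both by back-substitution
(predicting the training samples) and by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .diversity import DiversityIndices

__all__ = [
    "CorrelationSweep",
    "ClassificationResult",
    "pearson",
    "correlation_sweep",
    "welch_t_less",
    "lda_evaluate",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; hard error on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class CorrelationSweep:
    """Per-q correlation of D(q) with each diversity index across samples."""

    q_values: np.ndarray
    r_richness: np.ndarray
    r_shannon: np.ndarray
    r_simpson: np.ndarray

    def argmax_q(self, index: str) -> float:
        """q at which the correlation with ``index`` peaks."""
        r = getattr(self, f"r_{index}")
        return float(self.q_values[int(np.argmax(r))])

    def max_r(self, index: str) -> float:
        return float(np.max(getattr(self, f"r_{index}")))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q_values,
                "r_richness": self.r_richness,
                "r_shannon": self.r_shannon,
                "r_simpson": self.r_simpson,
            }
        )

    def save_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def correlation_sweep(
    spectra: np.ndarray,
    indices: Sequence[DiversityIndices],
    q_values: Sequence[float],
) -> CorrelationSweep:
    """Correlate each D(q) column with richness/Shannon/Simpson.

    ``spectra`` is an (n_samples, n_q) matrix of D(q) values on a common
    q grid; ``indices`` gives the per-sample diversity indices.
    """
    spectra = np.asarray(spectra, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != q.size:
        raise ValueError("spectra must be (n_samples, n_q) matching q_values")
    if spectra.shape[0] != len(indices):
        raise ValueError("one DiversityIndices per sample required")
    if spectra.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    rich = np.array([d.richness for d in indices], dtype=float)
    shan = np.array([d.shannon for d in indices], dtype=float)
    simp = np.array([d.simpson for d in indices], dtype=float)
    out = {}
    for name, vec in (("richness", rich), ("shannon", shan), ("simpson", simp)):
        out[name] = np.array([pearson(spectra[:, j], vec) for j in range(q.size)])
    return CorrelationSweep(q, out["richness"], out["shannon"], out["simpson"])


def welch_t_less(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """One-sided two-sample t-test with alternative mean(x) < mean(y).

    Welch's unequal-variance form by default (Welch-Satterthwaite
    degrees of freedom); ``equal_var=True`` gives the pooled-variance
    Student test. Returns ``(t, p)`` with ``p = P(T <= t)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("t-test undefined: both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=equal_var, alternative="less")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClassificationResult:
    """Back-substitution confusion matrix and LOOCV accuracy of an LDA fit."""

    classes: list[str]
    confusion: np.ndarray  # true x predicted
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    loocv_accuracy: float

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)

    def save_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.confusion_frame().to_csv(path, sep="\t", index_label="true\\predicted")
        return path


def _make_lda(shrinkage: str | float | None) -> LinearDiscriminantAnalysis:
    # lsqr + shrinkage keeps the pooled covariance invertible when the
    # number of D(q) features approaches the per-class sample count
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)


def lda_evaluate(
    features: np.ndarray,
    labels: Sequence[str],
    shrinkage: str | float | None = "auto",
) -> ClassificationResult:
    """Gaussian LDA with class-proportion priors, evaluated two ways.

    Back-substitution fits on all samples and predicts them (the
    confusion matrix rows are true classes, columns predictions);
    leave-one-out cross-validation refits n times, each sample predicted
    by the model trained on the others. ``shrinkage='auto'`` uses the
    Ledoit-Wolf analytic rule; pass a float in [0, 1] for fixed
    intensity or None for the unregularized pooled covariance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")

    if shrinkage is None:
        centered = np.concatenate(
            [X[y == c] - X[y == c].mean(axis=0) for c in classes]
        )
        pooled = centered.T @ centered / (X.shape[0] - classes.size)
        if np.linalg.matrix_rank(pooled) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; use shrinkage or reduce the feature count"
            )

    model = _make_lda(shrinkage)
    model.fit(X, y)
    back_pred = model.predict(X)
    loo_pred = cross_val_predict(_make_lda(shrinkage), X, y, cv=LeaveOneOut())

    conf = confusion_matrix(y, back_pred, labels=classes)
    per_class = conf.diagonal() / conf.sum(axis=1)
    return ClassificationResult(
        classes=[str(c) for c in classes],
        confusion=conf,
        per_class_accuracy=per_class,
        overall_accuracy=float(conf.diagonal().sum() / conf.sum()),
        loocv_accuracy=float(np.mean(loo_pred == y)),
    )
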