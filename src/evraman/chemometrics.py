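"""Multivariate statistics: PCA, Fisher LDA, LOOCV, confusion metrics.

The classification chain is the standard chemometric PCA-LDA: principal
component analysis of the mean-centred (unscaled) spectra reduces the
dimension, the leading scores feed a Fisher linear discriminant model, and
leave-one-out cross-validation (LOOCV) estimates sensitivity, specificity
and accuracy per class.  One-way ANOVA on single-component scores and the
multivariate Wilks' Lambda test quantify group separation.

Two LOOCV protocols are provided.  ``paper`` fits the PCA once on the full
cohort and cross-validates only the LDA on the resulting scores — the usual
practice in spectroscopy software, which leaks a small amount of information
through the shared decomposition.  ``strict`` refits the PCA inside every
fold and projects the held-out spectrum onto the training-only model,
quantifying that leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .spectra import SpectralDataset

__all__ = [
    "PCAModel",
    "LDAModel",
    "ConfusionMatrix",
    "ClassMetrics",
    "AnovaResult",
    "WilksResult",
    "fit_pca",
    "fit_lda",
    "loocv_classify",
    "confusion_metrics",
    "anova_scores",
    "wilks_test",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Covariance-based PCA of a spectral matrix.

    ``loadings`` holds k orthonormal rows (PC1..PCk, each sign-fixed so its
    largest-magnitude element is positive); ``var_fraction`` is each
    component's share of the *total* variance, so the fractions over all
    min(n-1, p) components sum to one.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    var_fraction: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.mean_spectrum) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.loadings + self.mean_spectrum


def fit_pca(d, k: int) -> PCAModel:
    """Fit a k-component PCA to a dataset or raw n x p matrix.

    Columns are mean-centred but not variance-scaled: after unit-vector
    normalisation all channels share one intensity scale, and scaling would
    inflate noise-only channels.
    """
    X = d.matrix if isinstance(d, SpectralDataset) else np.asarray(d, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} not in [1, min(n-1, p)={min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = Vt[:k].copy()
    scores = (U[:, :k] * s[:k]).copy()
    # deterministic sign: largest-magnitude element of each loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    if total == 0.0:
        var_fraction = np.zeros(k)
    else:
        var_fraction = s[:k] ** 2 / total
    return PCAModel(mean, loadings, scores, var_fraction)


# ---------------------------------------------------------------------------
# LDA

def _scatter_matrices(X: np.ndarray, labels: np.ndarray, classes):
    """Within-class and between-class scatter matrices."""
    k = X.shape[1]
    grand = X.mean(axis=0)
    W = np.zeros((k, k))
    B = np.zeros((k, k))
    means = {}
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        means[c] = mc
        D = Xc - mc
        W += D.T @ D
        dm = (mc - grand)[:, None]
        B += len(Xc) * (dm @ dm.T)
    return W, B, means


@dataclass
class LDAModel:
    """Fisher linear discriminant model on PC-score vectors.

    Discriminant axes are the leading generalised eigenvectors of the
    between-class scatter B against the (ridge-stabilised) within-class
    scatter W; prediction assigns the nearest class mean in discriminant
    space, breaking exact ties toward the lexicographically smaller label.
    """

    classes: list
    class_means: dict
    discriminants: np.ndarray  # m x k, rows are axes
    eigenvalues: np.ndarray
    wilks_lambda: float
    n_pcs: int = 25

    def project(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.discriminants.T

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.project(X)
        centers = np.stack([self.class_means[c] for c in self.classes]) @ self.discriminants.T
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # argmin returns the first minimum; classes are sorted, so exact ties
        # resolve to the lexicographically smaller label
        idx = np.argmin(d2, axis=1)
        return np.array([self.classes[i] for i in idx], dtype=object)


def fit_lda(scores: np.ndarray, labels, ridge: float = 1e-8) -> LDAModel:
    """Fit Fisher LDA to n x k score vectors with class labels."""
    X = np.asarray(scores, float)
    if X.ndim != 2:
        raise ValueError("scores must be an n x k matrix")
    labels = np.asarray(labels, dtype=object)
    n, k = X.shape
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
    if k >= n:
        raise ValueError(f"need fewer variables than observations (k={k}, n={n})")

    W, B, means = _scatter_matrices(X, labels, classes)
    Wr = W + ridge * np.eye(k)
    if ridge == 0.0:
        if np.linalg.matrix_rank(W) < k:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; pass a small ridge > 0"
            )
    evals, evecs = sla.eigh(B, Wr)  # ascending
    m = min(len(classes) - 1, k)
    order = np.argsort(evals)[::-1][:m]
    axes = evecs[:, order].T.copy()
    evals = evals[order].copy()
    for j in range(m):  # deterministic orientation and unit scale
        axes[j] /= np.linalg.norm(axes[j])
        i = int(np.argmax(np.abs(axes[j])))
        if axes[j, i] < 0:
            axes[j] *= -1.0

    sW, ldW = np.linalg.slogdet(W)
    sT, ldT = np.linalg.slogdet(W + B)
    lam = float(np.exp(ldW - ldT)) if (sW > 0 and sT > 0) else 0.0
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    return LDAModel(classes, means, axes, evals, lam, n_pcs=k)


# ---------------------------------------------------------------------------
# confusion matrix and metrics

@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class."""

    classes: list
    counts: np.ndarray

    def __post_init__(self):
        self.classes = list(self.classes)
        self.counts = np.asarray(self.counts)
        g = len(self.classes)
        if self.counts.shape != (g, g):
            raise ValueError("counts must be square and match the class list")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(int)

    @classmethod
    def from_predictions(cls, true, predicted, classes=None) -> "ConfusionMatrix":
        true = np.asarray(true, object)
        predicted = np.asarray(predicted, object)
        if classes is None:
            classes = sorted(set(true) | set(predicted))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), int)
        for t, p in zip(true, predicted):
            counts[index[t], index[p]] += 1
        return cls(list(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassMetrics:
    """One-vs-rest sensitivity/specificity/accuracy per class, in percent.

    Per-class values and the unweighted (macro) means are rounded half-up to
    one decimal, the convention of clinical-performance tables; ``raw``
    retains the unrounded values.
    """

    classes: list
    sensitivity: dict
    specificity: dict
    accuracy: dict
    macro_sensitivity: float
    macro_specificity: float
    macro_accuracy: float
    raw: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class and macro metrics from a confusion matrix.

    For class c: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/n, all one-vs-rest.  A class with no true instances
    has undefined sensitivity; macro averages then cover the defined classes
    only, with a warning recorded.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    C = cm.counts
    notes = []
    sens_raw, spec_raw, acc_raw = {}, {}, {}
    for i, c in enumerate(cm.classes):
        TP = C[i, i]
        FN = C[i].sum() - TP
        FP = C[:, i].sum() - TP
        TN = n - TP - FN - FP
        if TP + FN == 0:
            notes.append(f"class {c!r} has no true instances; sensitivity undefined")
            sens_raw[c] = None
        else:
            sens_raw[c] = 100.0 * TP / (TP + FN)
        spec_raw[c] = 100.0 * TN / (TN + FP) if TN + FP else None
        acc_raw[c] = 100.0 * (TP + TN) / n
    if notes:
        warnings.warn("; ".join(notes), stacklevel=2)

    def macro(d):
        vals = [v for v in d.values() if v is not None]
        return float(np.mean(vals))

    rounded = lambda d: {c: (None if v is None else _round_half_up(v))
                         for c, v in d.items()}
    return ClassMetrics(
        classes=list(cm.classes),
        sensitivity=rounded(sens_raw),
        specificity=rounded(spec_raw),
        accuracy=rounded(acc_raw),
        macro_sensitivity=_round_half_up(macro(sens_raw)),
        macro_specificity=_round_half_up(macro(spec_raw)),
        macro_accuracy=_round_half_up(macro(acc_raw)),
        raw={"sensitivity": sens_raw, "specificity": spec_raw, "accuracy": acc_raw},
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# LOOCV

def loocv_classify(d, labels=None, n_pcs: int = 25,
                   mode: str = "paper", ridge: float = 1e-8) -> ConfusionMatrix:
    """Leave-one-out cross-validated PCA-LDA classification.

    ``paper`` mode fits the PCA once on all n spectra and refits only the
    LDA on each fold's n-1 score vectors; ``strict`` mode also refits the
    PCA per fold and projects the held-out spectrum onto the training model.
    """
    if mode not in ("paper", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    X = d.matrix if isinstance(d, SpectralDataset) else np.asarray(d, float)
    if labels is None:
        if not isinstance(d, SpectralDataset):
            raise ValueError("labels required for a raw matrix")
        labels = d.labels
    labels = np.asarray(labels, dtype=object)
    n = X.shape[0]
    classes = sorted(set(labels))
    if n < len(classes) + 2:
        raise ValueError("too few spectra for LOOCV")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    thin = [c for c, m in counts.items() if m < 2]
    if thin:
        raise ValueError(f"classes {thin} would vanish from a training fold")

    predictions = np.empty(n, dtype=object)
    if mode == "paper":
        scores = fit_pca(X, n_pcs).scores
        for i in range(n):
            keep = np.arange(n) != i
            model = fit_lda(scores[keep], labels[keep], ridge=ridge)
            predictions[i] = model.predict(scores[i])[0]
    else:
        for i in range(n):
            keep = np.arange(n) != i
            pca = fit_pca(X[keep], n_pcs)
            model = fit_lda(pca.scores, labels[keep], ridge=ridge)
            predictions[i] = model.predict(pca.transform(X[i]))[0]
    return ConfusionMatrix.from_predictions(labels, predictions, classes)


# ---------------------------------------------------------------------------
# univariate and multivariate separation tests

@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    infinite: bool = False

    def __iter__(self):
        return iter((self.F, self.p))


def anova_scores(scores, labels) -> AnovaResult:
    """Classical one-way ANOVA of a score vector across class labels."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = [scores[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 members")
    n, g = len(scores), len(classes)
    ssw = sum(float(((x - x.mean()) ** 2).sum()) for x in groups)
    if ssw == 0.0:
        grand = scores.mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
        if ssb == 0.0:  # all values identical: no variance at all
            return AnovaResult(0.0, 1.0, g - 1, n - g)
        return AnovaResult(np.inf, 0.0, g - 1, n - g, infinite=True)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(float(F), float(p), g - 1, n - g)


@dataclass
class WilksResult:
    lam: float
    statistic: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.lam, self.p))


def wilks_test(scores, labels) -> WilksResult:
    """Wilks' Lambda = det(W)/det(W+B) with Bartlett's chi-square p-value.

    The test statistic is -(n - 1 - (k + g)/2) ln(Lambda) on k(g-1) degrees
    of freedom, where k is the score dimension and g the number of groups.
    """
    X = np.atleast_2d(np.asarray(scores, float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("Wilks test needs at least 2 groups")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
    n, k = X.shape
    g = len(classes)
    W, B, _ = _scatter_matrices(X, labels, classes)
    sT, ldT = np.linalg.slogdet(W + B)
    if sT <= 0:
        raise np.linalg.LinAlgError("total scatter matrix is singular")
    sW, ldW = np.linalg.slogdet(W)
    if sW <= 0:
        lam = float(np.finfo(float).tiny)
    else:
        lam = float(np.exp(ldW - ldT))
    lam = min(lam, 1.0)
    stat = -(n - 1 - (k + g) / 2.0) * np.log(lam)
    df = k * (g - 1)
    p = float(stats.chi2.sf(stat, df))
    return WilksResult(lam, float(stat), df, p)
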