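"""Classification of embedded points and every reported metric.

A one-vs-all Gaussian-kernel SVM (kernel scale 0.35, i.e. gamma = 1/σ²)
labels the 2-D map points; leave-one-out cross-validation and held-out
test evaluation produce confusion matrices, per-class true-positive
rates, the overall success ratio (OSR, the diagonal fraction in
percent), and the quality ratio QR = (OSR_LOOCV + OSR_TS)/2 used to rank
experiment configurations.  ROC curves carry percentile-bootstrap 95%
bands; two-sample Kolmogorov–Smirnov tests compare success-rate
distributions between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

CLASSES = ("S_H", "S_PD", "S_DBS")


@dataclass
class ConfusionMatrix:
    """Predicted × target counts over a fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("invalid confusion counts")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         classes: tuple[str, ...] = CLASSES) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[p], idx[t]] += 1   # rows: predicted, cols: target
        return cls(counts=counts, classes=classes)

    @property
    def tns(self) -> int:
        return int(self.counts.sum())

    def tp(self, cls_name: str) -> int:
        i = self.classes.index(cls_name)
        return int(self.counts[i, i])

    def fp(self, cls_name: str) -> int:
        i = self.classes.index(cls_name)
        return int(self.counts[i].sum() - self.counts[i, i])

    def fn(self, cls_name: str) -> int:
        i = self.classes.index(cls_name)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, cls_name: str) -> int:
        return self.tns - self.tp(cls_name) - self.fp(cls_name) - self.fn(cls_name)

    def tp_rate(self, cls_name: str) -> float:
        i = self.classes.index(cls_name)
        col = self.counts[:, i].sum()
        return float(self.counts[i, i] / col) if col else np.nan

    def column_normalized(self) -> np.ndarray:
        col = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, self.counts / col, np.nan)


@dataclass
class OneVsAllSVM:
    """Three binary Gaussian-kernel SVMs; prediction by largest decision
    value, ties broken by class order.

    Map coordinates are z-scored internally (fit on the training
    points): the kernel scale is specified relative to standardized 2-D
    coordinates, which keeps it meaningful across embedding methods
    whose raw coordinate scales differ by orders of magnitude.
    """

    kernel_scale: float = 0.35
    C: float = 1.0
    classes: tuple[str, ...] = CLASSES
    _models: dict | None = None
    _mu: np.ndarray | None = None
    _sd: np.ndarray | None = None

    def _standardize(self, points: np.ndarray) -> np.ndarray:
        return (points - self._mu) / self._sd

    def fit(self, points: np.ndarray, labels) -> "OneVsAllSVM":
        points = np.asarray(points, dtype=float)
        labels = np.asarray(labels)
        present = [c for c in self.classes if np.any(labels == c)]
        if len(present) < 2:
            raise ValueError("need at least 2 classes to train")
        self._mu = points.mean(axis=0)
        sd = points.std(axis=0, ddof=1)
        self._sd = np.where(sd > 0, sd, 1.0)
        pts = self._standardize(points)
        gamma = 1.0 / self.kernel_scale**2
        self._models = {}
        for c in present:
            y = (labels == c).astype(int)
            m = SVC(kernel="rbf", gamma=gamma, C=self.C)
            m.fit(pts, y)
            self._models[c] = m
        return self

    def decision_values(self, points: np.ndarray) -> np.ndarray:
        """n × k decision values (absent classes get −inf)."""
        points = self._standardize(np.asarray(points, dtype=float))
        out = np.full((points.shape[0], len(self.classes)), -np.inf)
        for j, c in enumerate(self.classes):
            if c in self._models:
                m = self._models[c]
                if len(m.classes_) == 2:
                    out[:, j] = m.decision_function(points)
        return out

    def predict(self, points: np.ndarray) -> np.ndarray:
        dv = self.decision_values(points)
        # argmax returns the first (class-order) maximum: the tie-break.
        return np.array([self.classes[j] for j in dv.argmax(axis=1)])


def train_svm(points: np.ndarray, labels, kernel_scale: float = 0.35,
              C: float = 1.0) -> OneVsAllSVM:
    """Fit the one-vs-all Gaussian-kernel SVM on 2-D map points."""
    return OneVsAllSVM(kernel_scale=kernel_scale, C=C).fit(points, labels)


def loocv(points: np.ndarray, labels, kernel_scale: float = 0.35,
          C: float = 1.0) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Leave-one-out cross-validation: n refits, one held-out prediction
    each, confusion accumulated over all folds."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    n_classes = len(set(labels))
    if n < n_classes + 1:
        raise ValueError("too few samples for LOOCV")
    preds = []
    for i in range(n):
        mask = np.arange(n) != i
        fold_labels = labels[mask]
        if len(set(fold_labels)) < n_classes:
            warnings.warn(
                f"fold {i}: training set lost a class; predicting among "
                "remaining classes", stacklevel=2,
            )
        model = train_svm(points[mask], fold_labels, kernel_scale, C)
        preds.append(model.predict(points[i:i + 1])[0])
    cm = ConfusionMatrix.from_predictions(labels, preds)
    rtp = {c: cm.tp_rate(c) for c in cm.classes}
    return cm, rtp


def accuracy(cm: ConfusionMatrix, cls_name: str) -> float:
    """Per-class (TP + TN) / (TP + TN + FP + FN)."""
    if cm.tns == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp(cls_name) + cm.tn(cls_name)) / cm.tns


def osr(cm: ConfusionMatrix) -> float:
    """Overall success ratio in percent: 100 × Σ diagonal / TNS."""
    if cm.tns == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(cm.counts) / cm.tns)


def success_rate(rtp_values: np.ndarray) -> float:
    """Mean true-positive rate over the v × τ grid cells."""
    rtp_values = np.asarray(rtp_values, dtype=float)
    if rtp_values.size == 0:
        raise ValueError("empty grid slice")
    return float(rtp_values.mean())


def quality_ratio(osr_loocv: float, osr_ts: float) -> float:
    """QR = (OSR_LOOCV + OSR_TS) / 2, in percent."""
    for v in (osr_loocv, osr_ts):
        if not 0 <= v <= 100:
            raise ValueError("OSR values must be in [0, 100]")
    return (osr_loocv + osr_ts) / 2.0


def grand_average_confusion(cms: list[ConfusionMatrix]) -> np.ndarray:
    """Average of column-normalized confusion matrices over
    configurations (columns each sum to 1 before averaging)."""
    if not cms:
        raise ValueError("no confusion matrices")
    normed = [cm.column_normalized() for cm in cms]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(normed), axis=0)


def roc_auc_bootstrap(scores: np.ndarray, y_binary: np.ndarray,
                      replicas: int = 1000, seed: int = 0) -> dict:
    """One-vs-all ROC with AUC and a percentile-bootstrap 95% CI.

    Resampling unit is the sample.  Degenerate (constant) scores yield
    AUC 0.5 with ``flagged=True``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_binary, dtype=int)
    if len(set(y)) < 2:
        raise ValueError("both labels must be present")
    if np.ptp(scores) == 0:
        warnings.warn("degenerate scores: AUC defined as 0.5", stacklevel=2)
        return dict(fpr=np.array([0, 1]), tpr=np.array([0, 1]), auc=0.5,
                    ci=(np.nan, np.nan), flagged=True)
    fpr, tpr, _ = roc_curve(y, scores)
    auc_val = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    boots = []
    n = y.size
    for _ in range(replicas):
        idx = rng.integers(0, n, n)
        if len(set(y[idx])) < 2 or np.ptp(scores[idx]) == 0:
            continue
        boots.append(roc_auc_score(y[idx], scores[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return dict(fpr=fpr, tpr=tpr, auc=auc_val, ci=(float(lo), float(hi)),
                flagged=False)


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_normality(sample: np.ndarray) -> tuple[float, float]:
    """One-sample KS test of the z-scored sample against N(0, 1)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.std(ddof=1) == 0:
        raise ValueError("need >= 3 values with spread")
    z = (x - x.mean()) / x.std(ddof=1)
    res = stats.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)
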