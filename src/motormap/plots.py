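"""Figure helpers: embedding scatter plots with SVM decision-boundary
shading, ROC curves with bootstrap bands, and success-rate boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .evaluate import CLASSES, OneVsAllSVM

_GROUP_STYLE = {
    "S_H": dict(marker="^", color="tab:green"),
    "S_PD": dict(marker="*", color="tab:red"),
    "S_DBS": dict(marker="o", color="tab:blue"),
}


def scatter_with_boundary(points: np.ndarray, labels, model: OneVsAllSVM,
                          title: str = "", ax=None, grid_n: int = 200):
    """Scatter of 2-D map points over decision regions classified on a
    dense grid by the trained one-vs-all SVM."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    pad = 0.1 * np.ptp(pts, axis=0)
    xs = np.linspace(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0], grid_n)
    ys = np.linspace(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1], grid_n)
    XX, YY = np.meshgrid(xs, ys)
    Z = model.predict(np.column_stack([XX.ravel(), YY.ravel()]))
    Zi = np.array([CLASSES.index(z) for z in Z]).reshape(XX.shape)
    ax.contourf(XX, YY, Zi, levels=[-0.5, 0.5, 1.5, 2.5],
                colors=["#d5e8d4", "#f8cecc", "#dae8fc"], alpha=0.6)
    for g in CLASSES:
        mask = labels == g
        if mask.any():
            ax.scatter(pts[mask, 0], pts[mask, 1], s=18, label=g,
                       **_GROUP_STYLE[g])
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def roc_with_bands(roc_results: dict[str, dict], title: str = "", ax=None):
    """Per-class ROC curves; the AUC and its bootstrap CI go in the
    legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for cls_name, out in roc_results.items():
        lo, hi = out["ci"]
        ax.plot(out["fpr"], out["tpr"],
                label=f"{cls_name}: AUC {out['auc']:.2f} [{lo:.2f}, {hi:.2f}]")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def success_rate_boxplots(rates_by_method: dict[str, np.ndarray],
                          title: str = "", ax=None):
    """Boxplots of per-configuration true-positive success rates, one
    box per embedding method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    names = list(rates_by_method)
    ax.boxplot([np.asarray(rates_by_method[m], dtype=float) for m in names],
               tick_labels=names)
    ax.set_ylabel("true-positive success rate")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    return ax
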