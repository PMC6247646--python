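#!/usr/bin/env python
"""Render the evaluation report: embedding scatter plots with decision
boundaries, ROC curves with bootstrap confidence bands, success-rate
boxplots, the grand-average confusion matrices, and the KS comparison of
Sammon vs t-SNE success rates.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from motormap import (
    dataset, dimred, evaluate, features, plots, simulate,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=simulate.DEFAULT_CALIBRATION_SEED)
    ap.add_argument("--features", type=Path, default=None)
    ap.add_argument("--grid-results", type=Path,
                    default=Path("results/grid_results.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
    args = ap.parse_args()

    if args.features is not None:
        fm = features.FeatureMatrix.from_csv(args.features)
    else:
        cohort = simulate.generate_cohort(simulate.CohortSpec(seed=args.seed))
        fm = features.build_feature_matrix(cohort, ("FS", "IF"), "T1")
    split, _ = dataset.standardize_and_split(fm, seed=args.seed)
    X_train = split.train.values.to_numpy()
    y_train = split.train.labels.to_numpy()
    args.out.mkdir(parents=True, exist_ok=True)

    # One representative embedding per method, with SVM boundary shading.
    embeddings = {}
    scores, loadings, _ = dimred.pca_project(X_train, 2)
    embeddings["PCA"] = scores
    embeddings["Sammon"] = dimred.sammon_map(
        X_train, iterations=423, learning_rate=0.4).coordinates
    embeddings["t-SNE"] = dimred.tsne_map(
        X_train, iterations=1000, learning_rate=300, perplexity=27,
        seed=args.seed).coordinates

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    confusions = {}
    for ax, (method, pts) in zip(axes, embeddings.items()):
        model = evaluate.train_svm(pts, y_train)
        cm, _ = evaluate.loocv(pts, y_train)
        confusions[method] = cm
        plots.scatter_with_boundary(
            pts, y_train, model,
            title=f"{method}: LOOCV OSR {evaluate.osr(cm):.1f}%", ax=ax)
    fig.tight_layout()
    fig.savefig(args.out / "embeddings_with_boundaries.svg")
    print(f"wrote {args.out / 'embeddings_with_boundaries.svg'}")

    # ROC with bootstrap bands for the t-SNE map (one-vs-all per class).
    pts = embeddings["t-SNE"]
    model = evaluate.train_svm(pts, y_train)
    dv = model.decision_values(pts)
    rocs = {}
    for j, cls_name in enumerate(evaluate.CLASSES):
        rocs[cls_name] = evaluate.roc_auc_bootstrap(
            dv[:, j], (y_train == cls_name).astype(int),
            replicas=1000, seed=args.seed)
    fig, ax = plt.subplots(figsize=(5, 4))
    plots.roc_with_bands(rocs, title="t-SNE map, LOOCV-style scores", ax=ax)
    fig.tight_layout()
    fig.savefig(args.out / "roc_tsne.svg")
    print(f"wrote {args.out / 'roc_tsne.svg'}")

    # Grand-average (column-normalized) confusion per method.
    rows = []
    for method, cm in confusions.items():
        avg = evaluate.grand_average_confusion([cm])
        for i, pred in enumerate(evaluate.CLASSES):
            rows.append(dict(method=method, predicted=pred,
                             **{t: round(avg[i, j], 2)
                                for j, t in enumerate(evaluate.CLASSES)}))
    pd.DataFrame(rows).to_csv(args.out.parent / "grand_average_confusion.csv",
                              index=False)

    # Success-rate boxplots + KS comparison from the grid ledger.
    if args.grid_results.exists():
        table = pd.read_csv(args.grid_results)
        ok = table[table["error"].isna()]
        rates = {m: ok.loc[ok["method"] == m, "osr_loocv"].to_numpy() / 100
                 for m in ("PCA", "Sammon", "t-SNE")}
        fig, ax = plt.subplots(figsize=(5, 4))
        plots.success_rate_boxplots(rates, title="LOOCV success rate", ax=ax)
        fig.tight_layout()
        fig.savefig(args.out / "success_rate_boxplots.svg")
        print(f"wrote {args.out / 'success_rate_boxplots.svg'}")
        if len(rates["Sammon"]) > 1 and len(rates["t-SNE"]) > 1:
            stat, p = evaluate.ks_compare(rates["Sammon"], rates["t-SNE"])
            print(f"KS Sammon vs t-SNE LOOCV success rates: "
                  f"D = {stat:.3f}, p = {p:.3g}")
    else:
        print(f"{args.grid_results} not found; run 03_run_grid.py first "
              "for boxplots and the KS comparison")


if __name__ == "__main__":
    main()
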