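#!/usr/bin/env python
"""Run the embedding/classification experiment grid and rank scenarios
by quality ratio.

Each configuration embeds the standardized training features in 2-D
(PCA, Sammon or t-SNE), maps the held-out 10% through the out-of-sample
network, classifies with the one-vs-all Gaussian SVM, and records LOOCV
and test overall success ratios plus their mean (QR).  The default is a
reduced grid on one feature matrix; --full enumerates the complete
28 + 700 + 3500 configuration space (long).
"""

import argparse
import itertools
import time
from pathlib import Path

import numpy as np

from motormap import dataset, features, grid, simulate


def reduced_configs() -> list[grid.ExperimentConfig]:
    combo, task = ("FS", "IF"), "T1"
    cfgs = [grid.ExperimentConfig("PCA", combo, task)]
    for l, eta in itertools.product((423, 742), (0.4, 0.6)):
        cfgs.append(grid.ExperimentConfig("Sammon", combo, task,
                                          iterations=l, learning_rate=eta,
                                          seed=l))
    for eta, eps in itertools.product((0.4, 0.6), (16, 27)):
        cfgs.append(grid.ExperimentConfig("t-SNE", combo, task,
                                          iterations=1000, learning_rate=eta,
                                          perplexity=eps, seed=1000 + eps))
    return cfgs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=simulate.DEFAULT_CALIBRATION_SEED)
    ap.add_argument("--features", type=Path, default=None,
                    help="feature CSV from 02_extract_features.py "
                         "(regenerated if omitted)")
    ap.add_argument("--full", action="store_true",
                    help="run the complete exhaustive grid (hours)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    if args.features is not None:
        fm = features.FeatureMatrix.from_csv(args.features)
    else:
        cohort = simulate.generate_cohort(simulate.CohortSpec(seed=args.seed))
        fm = features.build_feature_matrix(cohort, ("FS", "IF"), "T1")
    split, _ = dataset.standardize_and_split(fm, seed=args.seed)
    key = (tuple(fm.methods), fm.task)

    if args.full:
        spec = grid.GridSpec()
        cfgs = [c for m in grid.METHODS_DR
                for c in grid.enumerate_configs(spec, m, args.seed)
                if (tuple(c.preprocessing), c.task) == key]
    else:
        cfgs = reduced_configs()

    t0 = time.time()
    results = grid.run_grid({key: split}, cfgs)
    table = grid.results_table(results)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "grid_results.csv", index=False)

    ok = table[table["error"].isna()]
    print(f"{len(ok)}/{len(table)} configurations succeeded "
          f"({time.time() - t0:.0f}s)")
    print("\nmean QR per method:")
    print(ok.groupby("method")["qr"].agg(["mean", "std", "count"]).round(2))

    best = grid.select_best(results)
    rows = []
    for (task, method), r in sorted(best.items()):
        rows.append(dict(task=task, method=method,
                         iterations=r.config.iterations,
                         learning_rate=r.config.learning_rate,
                         perplexity=r.config.perplexity,
                         qr=round(r.qr, 2)))
    import pandas as pd
    pd.DataFrame(rows).to_csv(args.out / "best_scenarios.csv", index=False)
    print("\nbest scenario per (task, method) by QR:")
    print(pd.DataFrame(rows).to_string(index=False))


if __name__ == "__main__":
    main()
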