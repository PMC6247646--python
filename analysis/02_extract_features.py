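#!/usr/bin/env python
"""Extract the time-domain feature matrix for one task and preprocessing
combination.

Twelve features per channel and representation (filtered signal,
instantaneous amplitude, instantaneous frequency) over the chosen task
window give 408, 816 or 1224 columns.  The matrix is written as CSV with
group/subject/repetition metadata columns.
"""

import argparse
import time
from pathlib import Path

from motormap import features, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=simulate.DEFAULT_CALIBRATION_SEED)
    ap.add_argument("--task", default="T1", choices=simulate.TASKS)
    ap.add_argument("--methods", default="FS,IF",
                    help="comma-separated subset of FS,IA,IF")
    ap.add_argument("--cohort", type=Path, default=None,
                    help="load a saved cohort instead of regenerating")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    combo = features.parse_combination(tuple(args.methods.split(",")))
    if args.cohort is not None:
        cohort = simulate.load_cohort(args.cohort)
    else:
        cohort = simulate.generate_cohort(simulate.CohortSpec(seed=args.seed))

    t0 = time.time()
    fm = features.build_feature_matrix(cohort, combo, args.task)
    name = f"features_{args.task}_{'-'.join(combo)}.csv"
    args.out.mkdir(parents=True, exist_ok=True)
    fm.to_csv(args.out / name)
    print(f"{fm.n_samples} samples x {fm.n_features} features "
          f"({time.time() - t0:.0f}s) -> {args.out / name}")


if __name__ == "__main__":
    main()
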