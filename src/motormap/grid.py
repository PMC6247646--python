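"""Exhaustive experiment grid over preprocessing, task and embedding
hyperparameters, scored by quality ratio.

Each configuration runs four stages: (1) dimensionality reduction on the
training features, (2) out-of-sample extension of the test features,
(3) one-vs-all SVM training and prediction, (4) performance indices
(LOOCV and test OSR, their mean QR, per-class true-positive rates).
Default value lists give 7·4 = 28 PCA, ×25 = 700 Sammon and ×5·25 = 3500
t-SNE configurations.
"""

from __future__ import annotations

import json
import traceback
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimred, evaluate, oos
from .dataset import SplitDataset
from .features import COMBINATIONS

METHODS_DR = ("PCA", "Sammon", "t-SNE")

DEFAULT_ITERATIONS = {
    "Sammon": (423, 575, 742, 1080, 5000),
    "t-SNE": (1000, 2000, 3000, 4000, 5000),
}
DEFAULT_LEARNING_RATES = (0.2, 0.3, 0.4, 0.5, 0.6)
DEFAULT_PERPLEXITIES = (5, 10, 16, 21, 27)


@dataclass(frozen=True)
class ExperimentConfig:
    """One grid cell.  Parameters irrelevant to the method are None."""

    method: str
    preprocessing: tuple[str, ...]
    task: str
    iterations: int | None = None
    learning_rate: float | None = None
    perplexity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS_DR:
            raise ValueError(f"unknown DR method {self.method!r}")
        if self.method == "PCA" and (
            self.iterations is not None or self.learning_rate is not None
            or self.perplexity is not None
        ):
            raise ValueError("PCA takes no iteration/rate/perplexity parameters")
        if self.method == "Sammon" and self.perplexity is not None:
            raise ValueError("Sammon takes no perplexity")

    def key(self) -> str:
        return json.dumps(
            [self.method, list(self.preprocessing), self.task, self.iterations,
             self.learning_rate, self.perplexity], sort_keys=True,
        )


@dataclass
class GridSpec:
    """Value lists for the exhaustive search."""

    preprocessing: tuple = COMBINATIONS
    tasks: tuple = ("T1", "T2", "T3", "T4")
    iterations: dict = field(default_factory=lambda: dict(DEFAULT_ITERATIONS))
    learning_rates: tuple = DEFAULT_LEARNING_RATES
    perplexities: tuple = DEFAULT_PERPLEXITIES
    #: Table-style η values are relative steps; t-SNE's raw step is
    #: η × tsne_base_learning_rate.
    tsne_base_learning_rate: float = 500.0

    @classmethod
    def from_json(cls, path: str | Path) -> "GridSpec":
        d = json.loads(Path(path).read_text())
        kw = {}
        if "preprocessing" in d:
            kw["preprocessing"] = tuple(tuple(c) for c in d["preprocessing"])
        for key in ("tasks", "learning_rates", "perplexities"):
            if key in d:
                kw[key] = tuple(d[key])
        if "iterations" in d:
            kw["iterations"] = {k: tuple(v) for k, v in d["iterations"].items()}
        if "tsne_base_learning_rate" in d:
            kw["tsne_base_learning_rate"] = d["tsne_base_learning_rate"]
        return cls(**kw)


@dataclass
class ExperimentResult:
    """Metrics of one executed configuration (or its failure record)."""

    config: ExperimentConfig
    confusion_loocv: evaluate.ConfusionMatrix | None = None
    confusion_test: evaluate.ConfusionMatrix | None = None
    rtp_loocv: dict | None = None
    rtp_test: dict | None = None
    osr_loocv: float = np.nan
    osr_test: float = np.nan
    qr: float = np.nan
    oos_r: float = np.nan
    oos_mse: float = np.nan
    final_cost: float = np.nan
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def enumerate_configs(spec: GridSpec, method: str,
                      master_seed: int = 0) -> list[ExperimentConfig]:
    """Full Cartesian product of the method's parameters, deterministic
    order, deduplicated.  Per-config seeds derive from (master seed,
    config key hash) so results are order-independent."""
    if method not in METHODS_DR:
        raise ValueError(f"unknown DR method {method!r}")
    if not spec.preprocessing or not spec.tasks:
        raise ValueError("empty preprocessing/task list")
    if method != "PCA":
        if not spec.iterations.get(method) or not spec.learning_rates:
            raise ValueError(f"empty parameter list for {method}")
    if method == "t-SNE" and not spec.perplexities:
        raise ValueError("empty perplexity list")

    configs, seen = [], set()
    for v in spec.preprocessing:
        for task in spec.tasks:
            if method == "PCA":
                cells = [(None, None, None)]
            elif method == "Sammon":
                cells = [(l, eta, None) for l in spec.iterations["Sammon"]
                         for eta in spec.learning_rates]
            else:
                cells = [(l, eta, eps) for l in spec.iterations["t-SNE"]
                         for eta in spec.learning_rates
                         for eps in spec.perplexities]
            for l, eta, eps in cells:
                cfg = ExperimentConfig(
                    method=method, preprocessing=tuple(v), task=task,
                    iterations=l, learning_rate=eta, perplexity=eps,
                )
                if cfg.key() in seen:
                    continue
                seen.add(cfg.key())
                seed = np.random.SeedSequence(
                    [master_seed, zlib.crc32(cfg.key().encode()) & 0x7FFFFFFF]
                ).generate_state(1)[0] & 0x7FFFFFFF
                configs.append(replace(cfg, seed=int(seed)))
    return configs


def run_experiment(config: ExperimentConfig, split: SplitDataset, *,
                   tsne_base_learning_rate: float = 500.0,
                   oos_hidden_units: int = 20, oos_max_iter: int = 60,
                   kernel_scale: float = 0.35, C: float = 1.0,
                   ) -> ExperimentResult:
    """Execute DR → out-of-sample → SVM → indices for one configuration.

    Any stage failure is recorded on the result instead of raised, so a
    grid run continues past broken cells.
    """
    try:
        if split.train.task and config.task and split.train.task != config.task:
            raise ValueError(
                f"split task {split.train.task!r} != config task {config.task!r}"
            )
        X_train = split.train.values.to_numpy()
        X_test = split.test.values.to_numpy()
        y_train = split.train.labels.to_numpy()
        y_test = split.test.labels.to_numpy()

        final_cost = np.nan
        oos_r = oos_mse = np.nan
        if config.method == "PCA":
            scores, loadings, evr = dimred.pca_project(X_train, 2)
            Y_train = scores
            Y_test = (X_test - X_train.mean(axis=0)) @ loadings
            final_cost = float(evr.sum())
        else:
            if config.method == "Sammon":
                emb = dimred.sammon_map(
                    X_train, iterations=config.iterations,
                    learning_rate=config.learning_rate, seed=config.seed,
                )
            else:
                emb = dimred.tsne_map(
                    X_train, iterations=config.iterations,
                    learning_rate=config.learning_rate * tsne_base_learning_rate,
                    perplexity=config.perplexity, seed=config.seed,
                )
            Y_train = emb.coordinates
            final_cost = emb.final_cost
            mapper = oos.fit_oos_mapper(
                X_train, Y_train, hidden_units=oos_hidden_units,
                max_iter=oos_max_iter, seed=config.seed,
            )
            oos_r, oos_mse = mapper.r_value, mapper.mse
            Y_test = oos.apply_oos(mapper, X_test)

        cm_loo, rtp_loo = evaluate.loocv(Y_train, y_train, kernel_scale, C)
        model = evaluate.train_svm(Y_train, y_train, kernel_scale, C)
        cm_test = evaluate.ConfusionMatrix.from_predictions(
            y_test, model.predict(Y_test)
        )
        rtp_test = {c: cm_test.tp_rate(c) for c in cm_test.classes}
        osr_loo = evaluate.osr(cm_loo)
        osr_test = evaluate.osr(cm_test)
        return ExperimentResult(
            config=config, confusion_loocv=cm_loo, confusion_test=cm_test,
            rtp_loocv=rtp_loo, rtp_test=rtp_test,
            osr_loocv=osr_loo, osr_test=osr_test,
            qr=evaluate.quality_ratio(osr_loo, osr_test),
            oos_r=oos_r, oos_mse=oos_mse, final_cost=final_cost,
        )
    except Exception as exc:  # failed configs are reported, never fatal
        return ExperimentResult(
            config=config,
            error=f"{type(exc).__name__}: {exc}\n{traceback.format_exc(limit=3)}",
        )


def run_grid(splits: dict, configs: list[ExperimentConfig],
             spec: GridSpec | None = None, **kwargs) -> list[ExperimentResult]:
    """Run configurations against their (preprocessing, task) splits.

    ``splits`` maps (preprocessing tuple, task) → SplitDataset.  Emits
    exactly one result record per configuration (success or failure).
    """
    base_lr = (spec.tsne_base_learning_rate if spec is not None
               else GridSpec().tsne_base_learning_rate)
    results = []
    for cfg in configs:
        key = (tuple(cfg.preprocessing), cfg.task)
        if key not in splits:
            results.append(ExperimentResult(
                config=cfg, error=f"KeyError: no split for {key}"))
            continue
        results.append(run_experiment(
            cfg, splits[key], tsne_base_learning_rate=base_lr, **kwargs))
    return results


def select_best(results: list[ExperimentResult],
                ) -> dict[tuple[str, str], ExperimentResult]:
    """Best configuration per (task, method) by QR; ties broken by fewer
    iterations, then lexicographic config order."""
    ok = [r for r in results if r.ok]
    if not ok:
        raise ValueError("no successful results")
    best: dict[tuple[str, str], ExperimentResult] = {}
    for r in ok:
        key = (r.config.task, r.config.method)
        cur = best.get(key)
        if cur is None:
            best[key] = r
            continue
        cand = (-r.qr, r.config.iterations or 0, r.config.key())
        incumbent = (-cur.qr, cur.config.iterations or 0, cur.config.key())
        if cand < incumbent:
            best[key] = r
    return best


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Flat per-config table (the Table 2-style report's raw material)."""
    rows = []
    for r in results:
        rows.append(dict(
            method=r.config.method,
            preprocessing="-".join(r.config.preprocessing),
            task=r.config.task,
            iterations=r.config.iterations,
            learning_rate=r.config.learning_rate,
            perplexity=r.config.perplexity,
            osr_loocv=r.osr_loocv, osr_test=r.osr_test, qr=r.qr,
            oos_r=r.oos_r, oos_mse=r.oos_mse, final_cost=r.final_cost,
            error=r.error,
        ))
    return pd.DataFrame(rows)
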