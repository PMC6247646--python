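"""Feature standardization (z-score) and the stratified 90/10 split.

The default ordering standardizes on the full dataset before splitting
(replicating the original protocol); a leak-free alternative that fits
the standardizer on the training portion only is available via
``split_first=True`` in :func:`standardize_and_split`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix


@dataclass
class StandardizationParams:
    """Per-feature mean and sample sd used for z-scoring."""

    mu: np.ndarray
    sigma: np.ndarray

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        sigma = np.where(self.sigma > 0, self.sigma, 1.0)
        vals = (matrix.values.to_numpy() - self.mu) / sigma
        vals[:, self.sigma == 0] = 0.0
        return FeatureMatrix(
            values=pd.DataFrame(vals, columns=matrix.values.columns),
            labels=matrix.labels.reset_index(drop=True),
            task=matrix.task,
            subjects=matrix.subjects,
            repetitions=matrix.repetitions,
            methods=matrix.methods,
        )


@dataclass
class SplitDataset:
    """Row-disjoint train/test partition, stratified by group."""

    train: FeatureMatrix
    test: FeatureMatrix
    split_seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def zscore_fit_apply(matrix: FeatureMatrix) -> tuple[FeatureMatrix, StandardizationParams]:
    """z = (x − μ)/σ per feature over all samples (sample-sd, n−1).

    Zero-variance columns are set to 0 with a warning.
    """
    X = matrix.values.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        warnings.warn(
            f"{int((sigma == 0).sum())} zero-variance feature(s) set to 0",
            stacklevel=2,
        )
    params = StandardizationParams(mu=mu, sigma=sigma)
    return params.apply(matrix), params


def _subset(matrix: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=matrix.values.iloc[idx].reset_index(drop=True),
        labels=matrix.labels.iloc[idx].reset_index(drop=True),
        task=matrix.task,
        subjects=matrix.subjects.iloc[idx].reset_index(drop=True)
        if matrix.subjects is not None else None,
        repetitions=matrix.repetitions.iloc[idx].reset_index(drop=True)
        if matrix.repetitions is not None else None,
        methods=matrix.methods,
    )


def stratified_split(matrix: FeatureMatrix, train_fraction: float = 0.9,
                     seed: int = 0) -> SplitDataset:
    """Seeded random split with per-group proportions respected.

    Per group, round(train_fraction × n) rows (round-half-to-even) go to
    train, the remainder to test.  Raises if any group is empty or the
    test set would be empty.
    """
    if not 0 < train_fraction < 1 + 1e-12:
        raise ValueError("train_fraction must be in (0, 1]")
    labels = matrix.labels.to_numpy()
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for group in pd.unique(labels):
        idx = np.flatnonzero(labels == group)
        if idx.size < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        n_train = int(np.round(train_fraction * idx.size))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    if test_idx.size == 0:
        raise ValueError("test set is empty; lower train_fraction")
    # Partition sanity: no row lost or duplicated.
    assert len(np.intersect1d(train_idx, test_idx)) == 0
    assert train_idx.size + test_idx.size == matrix.n_samples
    return SplitDataset(
        train=_subset(matrix, train_idx),
        test=_subset(matrix, test_idx),
        split_seed=seed,
        train_indices=train_idx,
        test_indices=test_idx,
    )


def standardize_and_split(matrix: FeatureMatrix, train_fraction: float = 0.9,
                          seed: int = 0, *, split_first: bool = False,
                          ) -> tuple[SplitDataset, StandardizationParams]:
    """Standardize-then-split (default, replicating the original
    protocol) or split-then-standardize (leak-free; the standardizer is
    fit on the training rows and applied to both partitions)."""
    if split_first:
        split = stratified_split(matrix, train_fraction, seed)
        train_std, params = zscore_fit_apply(split.train)
        return SplitDataset(
            train=train_std,
            test=params.apply(split.test),
            split_seed=seed,
            train_indices=split.train_indices,
            test_indices=split.test_indices,
        ), params
    std, params = zscore_fit_apply(matrix)
    return stratified_split(std, train_fraction, seed), params


def save_split_manifest(split: SplitDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(
        split_seed=split.split_seed,
        train_indices=split.train_indices.tolist(),
        test_indices=split.test_indices.tolist(),
    )))


def load_split_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
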