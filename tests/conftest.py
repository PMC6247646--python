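"""Shared fixtures: the calibrated default cohort and its feature/split
pipeline products are session-scoped because they are expensive."""

from __future__ import annotations

import numpy as np
import pytest

from motormap import dataset, features, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """The calibrated default cohort: 38 subjects x 5 repetitions."""
    return simulate.generate_cohort(simulate.CohortSpec())


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six subjects (2 per group), 2 repetitions: fast module-level data."""
    spec = simulate.CohortSpec(n_per_group=(2, 2, 2), repetitions=2, seed=7)
    with pytest.warns(UserWarning, match="repetitions"):
        return simulate.generate_cohort(spec)


@pytest.fixture(scope="session")
def fsif_t1_features(default_cohort):
    """FS-IF features on finger taps for the default cohort (the
    combination reported best by the original study)."""
    return features.build_feature_matrix(default_cohort, ("FS", "IF"), "T1")


@pytest.fixture(scope="session")
def default_split(fsif_t1_features):
    split, _ = dataset.standardize_and_split(
        fsif_t1_features, seed=simulate.DEFAULT_CALIBRATION_SEED
    )
    return split


def make_constant_recording(value: float, subject_id: int = 1,
                            group: str = "S_H", repetition: int = 1,
                            n_task: int = 100) -> simulate.RawRecording:
    """A recording whose channels are all the given constant (EMG
    channels clipped at 0): handy for arithmetic oracles."""
    profile = simulate.SubjectProfile(subject_id=subject_id, group=group)
    n = 4 * n_task
    channels = {
        name: np.full(n, max(value, 0.0) if name in simulate.EMG_CHANNELS else value)
        for name in simulate.CHANNELS
    }
    windows = {t: (i * n_task, (i + 1) * n_task)
               for i, t in enumerate(simulate.TASKS)}
    return simulate.RawRecording(
        subject=profile, repetition=repetition, channels=channels,
        task_windows=windows,
    )
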