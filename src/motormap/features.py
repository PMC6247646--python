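"""Signal preprocessing and time-domain feature extraction.

Three per-channel representations feed the feature extractor:

* FS — the filtered signal (zero-phase 4th-order Butterworth low-pass at
  15 Hz for inertial channels; EMG envelopes pass through unchanged);
* IA — instantaneous amplitude, the magnitude of the analytic signal;
* IF — instantaneous frequency, the scaled derivative of the unwrapped
  analytic phase.

Twelve time-domain features are computed per (channel, representation)
on each task window after trimming 0.5 s from each edge (Hilbert end
effects): MAV, RMS, PEAK, MAVSDN, MAVSD, MAVFDN, MAVFD, INTERQ_RANGE,
RANGE, STD, VAR and approximate entropy.  With 34 channels this yields
feature dimensionalities 408, 816 or 1224 depending on how many
representations are combined.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import CHANNELS, EMG_CHANNELS, RawRecording

METHODS = ("FS", "IA", "IF")

#: The 7 admissible preprocessing combinations.
COMBINATIONS = (
    ("FS",), ("IA",), ("IF",),
    ("FS", "IA"), ("FS", "IF"), ("IA", "IF"),
    ("FS", "IA", "IF"),
)

FEATURE_NAMES = (
    "MAV", "RMS", "PEAK", "MAVSDN", "MAVSD", "MAVFDN", "MAVFD",
    "INTERQ_RANGE", "RANGE", "STD", "VAR", "APEN",
)


def parse_combination(spec: str | tuple) -> tuple[str, ...]:
    """Normalize 'FS-IA' / ('FS','IA') into a canonical method tuple."""
    if isinstance(spec, str):
        parts = tuple(spec.split("-"))
    else:
        parts = tuple(spec)
    parts = tuple(m for m in METHODS if m in parts)
    if not parts or parts not in COMBINATIONS:
        raise ValueError(f"invalid preprocessing combination: {spec!r}")
    return parts


def hilbert_ia_if(x: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and frequency from the analytic signal.

    IA is the analytic-signal magnitude; IF the central-difference
    derivative of the unwrapped phase, scaled to Hz.  A constant series
    has IA = |offset| and IF defined as 0 (with a warning).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for analytic-signal estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IF defined as 0", stacklevel=2)
        return np.full_like(x, abs(x[0])), np.zeros_like(x)
    analytic = sps.hilbert(x)
    ia = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    if_hz = np.gradient(phase) * sample_rate / (2 * np.pi)
    return ia, if_hz


def resultant(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of three axis series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must have equal length")
    return np.sqrt(x**2 + y**2 + z**2)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) with self-matches counted.

    ``r`` defaults to 0.2 × sample sd of the signal; a zero-variance
    signal under the relative default gets an r floor and returns 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the requested embedding")
    if r is None:
        sd = x.std(ddof=1)
        r = 0.2 * sd if sd > 0 else 1e-12
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        n_vec = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)  # (n_vec, mm)
        # Chebyshev distances via per-dimension broadcasting.
        dist = np.abs(emb[:, None, 0] - emb[None, :, 0])
        for j in range(1, mm):
            np.maximum(dist, np.abs(emb[:, None, j] - emb[None, :, j]), out=dist)
        c = (dist <= r).mean(axis=1)  # self-match included
        return float(np.mean(np.log(c)))

    return max(0.0, phi(m) - phi(m + 1))


def extract_features(window: np.ndarray, *, apen_m: int = 2,
                     apen_r_factor: float = 0.2) -> np.ndarray:
    """The ordered 12-feature vector for one window.

    Normalized variants (MAVSDN, MAVFDN) are computed on the z-scored
    window; differences are first/second discrete differences; STD/VAR
    use the sample (n−1) convention.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 4:
        raise ValueError("window too short")
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite values in window")

    sd = w.std(ddof=1)
    z = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
    d1, d2 = np.diff(w), np.diff(w, n=2)
    zd1, zd2 = np.diff(z), np.diff(z, n=2)
    q75, q25 = np.percentile(w, [75, 25])
    apen_r = apen_r_factor * sd if sd > 0 else 1e-12
    apen = (
        approximate_entropy(w, m=apen_m, r=apen_r)
        if sd > 0 else 0.0
    )
    return np.array([
        np.mean(np.abs(w)),            # MAV
        np.sqrt(np.mean(w**2)),        # RMS
        np.max(w),                     # PEAK
        np.mean(np.abs(zd2)),          # MAVSDN
        np.mean(np.abs(d2)),           # MAVSD
        np.mean(np.abs(zd1)),          # MAVFDN
        np.mean(np.abs(d1)),           # MAVFD
        q75 - q25,                     # INTERQ_RANGE
        np.ptp(w),                     # RANGE
        sd,                            # STD
        sd**2,                         # VAR
        apen,                          # APEN
    ])


def preprocess_channel(x: np.ndarray, channel: str, sample_rate: float,
                       method: str, *, lowpass_hz: float = 15.0,
                       filter_order: int = 4) -> np.ndarray:
    """One channel under one representation (FS, IA or IF)."""
    if method == "FS":
        if channel in EMG_CHANNELS:
            return np.asarray(x, dtype=float)  # already an envelope
        nyq = sample_rate / 2.0
        b, a = sps.butter(filter_order, lowpass_hz / nyq, btype="low")
        return sps.filtfilt(b, a, x)
    if method == "IA":
        return hilbert_ia_if(x, sample_rate)[0]
    if method == "IF":
        return hilbert_ia_if(x, sample_rate)[1]
    raise ValueError(f"unknown preprocessing method {method!r}")


@dataclass
class FeatureMatrix:
    """Samples × features table with group labels and sample metadata.

    One row per (subject, repetition); columns are named
    ``FEATURE|channel|method``.
    """

    values: pd.DataFrame
    labels: pd.Series
    task: str
    subjects: pd.Series | None = None
    repetitions: pd.Series | None = None
    methods: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.labels) != len(self.values):
            raise ValueError("labels/rows mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.insert(0, "__label__", self.labels.to_numpy())
        df.insert(1, "__task__", self.task)
        if self.subjects is not None:
            df.insert(2, "__subject__", self.subjects.to_numpy())
        if self.repetitions is not None:
            df.insert(3, "__repetition__", self.repetitions.to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = [c for c in df.columns if c.startswith("__")]
        task = str(df["__task__"].iloc[0]) if "__task__" in meta else ""
        methods = tuple(
            dict.fromkeys(c.split("|")[2] for c in df.columns if c.count("|") == 2)
        )
        return cls(
            values=df.drop(columns=meta),
            labels=df["__label__"].reset_index(drop=True),
            task=task,
            subjects=df["__subject__"].reset_index(drop=True)
            if "__subject__" in meta else None,
            repetitions=df["__repetition__"].reset_index(drop=True)
            if "__repetition__" in meta else None,
            methods=methods,
        )

    @classmethod
    def from_xlsx(cls, path: str | Path, *, label_column: str = "group",
                  task: str = "", sheet_name=0) -> "FeatureMatrix":
        """Import a spreadsheet of precomputed feature vectors.

        Expects one row per sample, a label column with group names, and
        numeric feature columns (any other non-numeric columns are kept
        out of the feature block).
        """
        df = pd.read_excel(path, sheet_name=sheet_name)
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column].astype(str).reset_index(drop=True)
        feats = df.drop(columns=[label_column]).select_dtypes(include=[np.number])
        return cls(values=feats.reset_index(drop=True), labels=labels, task=task)


def build_feature_matrix(recordings: list[RawRecording],
                         combination: str | tuple, task: str, *,
                         edge_trim_s: float = 0.5,
                         lowpass_hz: float = 15.0,
                         apen_m: int = 2,
                         apen_r_factor: float = 0.2) -> FeatureMatrix:
    """Assemble the samples × (12 × 34 × |combination|) feature matrix
    for one task window.

    Column order is deterministic: methods in canonical order, channels
    in the fixed inventory order, features in ``FEATURE_NAMES`` order.
    Row order follows the input recording order.
    """
    methods = parse_combination(combination)
    if not recordings:
        raise ValueError("no recordings")
    rows, labels, subjects, repetitions = [], [], [], []
    columns = [
        f"{feat}|{ch}|{meth}"
        for meth in methods
        for ch in CHANNELS
        for feat in FEATURE_NAMES
    ]
    for rec in recordings:
        if set(rec.channels) != set(CHANNELS):
            raise ValueError("recording channel layout mismatch")
        sl = rec.task_slice(task)
        if sl.stop - sl.start <= 0:
            raise ValueError(f"empty task window {task}")
        trim = int(round(edge_trim_s * rec.sample_rate))
        if sl.stop - sl.start <= 2 * trim + 4:
            raise ValueError("task window too short after edge trimming")
        row = np.empty(len(columns))
        i = 0
        for meth in methods:
            for ch in CHANNELS:
                pre = preprocess_channel(
                    rec.channels[ch][sl], ch, rec.sample_rate, meth,
                    lowpass_hz=lowpass_hz,
                )
                w = pre[trim:len(pre) - trim]
                row[i:i + 12] = extract_features(
                    w, apen_m=apen_m, apen_r_factor=apen_r_factor
                )
                i += 12
        rows.append(row)
        labels.append(rec.subject.group)
        subjects.append(rec.subject.subject_id)
        repetitions.append(rec.repetition)

    values = pd.DataFrame(np.vstack(rows), columns=columns)
    return FeatureMatrix(
        values=values,
        labels=pd.Series(labels, name="group"),
        task=task,
        subjects=pd.Series(subjects, name="subject"),
        repetitions=pd.Series(repetitions, name="repetition"),
        methods=methods,
    )
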