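"""Feature extraction: analytic-signal amplitude/frequency, the twelve
time-domain statistics against from-definition oracles, and feature
matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from motormap import features
from motormap.features import (
    FEATURE_NAMES,
    FeatureMatrix,
    approximate_entropy,
    build_feature_matrix,
    extract_features,
    hilbert_ia_if,
    resultant,
)

FS = 50.0


class TestHilbert:
    def test_pure_sinusoid_ia_if(self):
        t = np.arange(0, 10, 1 / FS)
        ia, if_hz = hilbert_ia_if(np.sin(2 * np.pi * 6 * t), FS)
        interior = slice(25, -25)
        assert np.allclose(ia[interior], 1.0, atol=0.05)
        assert np.allclose(if_hz[interior], 6.0, atol=0.1)

    def test_amplitude_modulation_tracked(self):
        t = np.arange(0, 10, 1 / FS)
        a = 1.0 + 0.4 * np.sin(2 * np.pi * 0.2 * t)
        ia, _ = hilbert_ia_if(a * np.sin(2 * np.pi * 6 * t), FS)
        interior = slice(25, -25)
        rel = np.abs(ia[interior] - a[interior]) / a[interior]
        assert rel.max() < 0.05

    def test_chirp_if_monotone(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * (2 * t + (8 - 2) / (2 * 10) * t**2))
        _, if_hz = hilbert_ia_if(x, FS)
        interior = if_hz[25:-25]
        # ripple rides on the rising trend; per-second means are clean
        blocks = interior[: len(interior) // 50 * 50].reshape(-1, 50).mean(axis=1)
        assert np.all(np.diff(blocks) > 0)
        assert interior[-1] > interior[0] + 4

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            ia, if_hz = hilbert_ia_if(np.full(64, -3.0), FS)
        assert np.all(ia == 3.0) and np.all(if_hz == 0.0)


class TestResultant:
    def test_three_four_five(self):
        out = resultant(np.full(5, 3.0), np.full(5, 4.0), np.zeros(5))
        np.testing.assert_allclose(out, 5.0)

    def test_single_axis_identity(self):
        x = np.array([-2.0, 1.0, 0.0])
        np.testing.assert_allclose(resultant(x, 0 * x, 0 * x), np.abs(x))

    def test_random_against_per_sample_norm(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.standard_normal((3, 40))
        expected = np.array([np.linalg.norm([a, b, c])
                             for a, b, c in zip(x, y, z)])
        np.testing.assert_allclose(resultant(x, y, z), expected, rtol=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            resultant(np.zeros(3), np.zeros(4), np.zeros(3))


def _apen_bruteforce(x, m, r):
    """Independent O(n^2) double-loop ApEn (self-matches included)."""
    n = len(x)

    def phi(mm):
        vecs = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for vi in vecs:
            c = sum(
                1 for vj in vecs
                if max(abs(a - b) for a, b in zip(vi, vj)) <= r
            )
            total += np.log(c / len(vecs))
        return total / len(vecs)

    return phi(m) - phi(m + 1)


class TestApEn:
    def test_constant_is_zero(self):
        assert approximate_entropy(np.full(30, 1.5), m=2) == 0.0

    @pytest.mark.parametrize("series,m,r", [
        (np.tile([0.0, 1.0], 25), 2, 0.5),
        (np.random.default_rng(11).uniform(size=80), 2, 0.2),
        (np.random.default_rng(12).standard_normal(60), 3, 0.4),
    ])
    def test_matches_bruteforce_oracle(self, series, m, r):
        expected = max(0.0, _apen_bruteforce(series, m, r))
        assert approximate_entropy(series, m=m, r=r) == pytest.approx(
            expected, abs=1e-12
        )

    def test_noise_more_entropic_than_sinusoid(self):
        rng = np.random.default_rng(5)
        noise = rng.uniform(-1, 1, 300)
        t = np.arange(300) / FS
        sine = np.sin(2 * np.pi * 6 * t)
        r = 0.2 * np.std(noise, ddof=1)
        assert approximate_entropy(noise, 2, r) > approximate_entropy(sine, 2, r)


class TestExtractFeatures:
    def test_constant_window(self):
        v = dict(zip(FEATURE_NAMES, extract_features(np.ones(10))))
        assert v["MAV"] == v["RMS"] == v["PEAK"] == 1.0
        assert v["RANGE"] == v["STD"] == v["VAR"] == v["APEN"] == 0.0

    def test_two_point_window_sample_convention(self):
        v = dict(zip(FEATURE_NAMES, extract_features(np.array([0.0, 2.0, 0.0, 2.0]))))
        w = np.array([0.0, 2.0, 0.0, 2.0])
        assert v["STD"] == pytest.approx(w.std(ddof=1))
        assert v["VAR"] == pytest.approx(w.var(ddof=1))
        assert v["RANGE"] == 2.0

    def test_every_statistic_matches_definition(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            w = rng.standard_normal(rng.integers(30, 80))
            got = dict(zip(FEATURE_NAMES, extract_features(w)))
            sd = w.std(ddof=1)
            z = (w - w.mean()) / sd
            q75, q25 = np.percentile(w, [75, 25])
            expected = {
                "MAV": np.mean(np.abs(w)),
                "RMS": np.sqrt(np.mean(w**2)),
                "PEAK": w.max(),
                "MAVSDN": np.mean(np.abs(np.diff(z, n=2))),
                "MAVSD": np.mean(np.abs(np.diff(w, n=2))),
                "MAVFDN": np.mean(np.abs(np.diff(z))),
                "MAVFD": np.mean(np.abs(np.diff(w))),
                "INTERQ_RANGE": q75 - q25,
                "RANGE": w.max() - w.min(),
                "STD": sd,
                "VAR": sd**2,
                "APEN": max(0.0, _apen_bruteforce(w, 2, 0.2 * sd)),
            }
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, abs=1e-10), name

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.array([1.0, np.nan, 2.0, 3.0]))


class TestBuildFeatureMatrix:
    @pytest.mark.parametrize("combo,expected_d", [
        (("FS",), 408),
        ("FS-IF", 816),
        (("FS", "IA", "IF"), 1224),
    ])
    def test_dimensionality(self, tiny_cohort, combo, expected_d):
        fm = build_feature_matrix(tiny_cohort[:2], combo, "T1")
        assert fm.n_features == expected_d
        assert fm.n_samples == 2

    def test_row_order_follows_input(self, tiny_cohort):
        fm = build_feature_matrix(tiny_cohort[:3], ("FS",), "T2")
        expected = [(r.subject.subject_id, r.repetition) for r in tiny_cohort[:3]]
        got = list(zip(fm.subjects, fm.repetitions))
        assert got == expected

    def test_column_order_deterministic(self, tiny_cohort):
        a = build_feature_matrix(tiny_cohort[:2], ("FS", "IF"), "T1")
        b = build_feature_matrix(tiny_cohort[:2], ("FS", "IF"), "T1")
        assert list(a.values.columns) == list(b.values.columns)
        assert a.values.columns[0] == f"{FEATURE_NAMES[0]}|hand_acc_x|FS"

    def test_invalid_combination_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            build_feature_matrix(tiny_cohort[:2], ("XX",), "T1")


class TestFeatureMatrixIO:
    def test_csv_roundtrip(self, tiny_cohort, tmp_path):
        fm = build_feature_matrix(tiny_cohort[:2], ("FS",), "T1")
        path = tmp_path / "f.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values.to_numpy(),
                                   fm.values.to_numpy(), rtol=1e-12)
        assert list(back.labels) == list(fm.labels)
        assert back.task == "T1"

    def test_xlsx_import(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((6, 4)),
                          columns=[f"feat{i}" for i in range(4)])
        df.insert(0, "group", ["S_H", "S_H", "S_PD", "S_PD", "S_DBS", "S_DBS"])
        path = tmp_path / "supp.xlsx"
        df.to_excel(path, index=False)
        fm = FeatureMatrix.from_xlsx(path, label_column="group")
        assert fm.n_samples == 6 and fm.n_features == 4
        assert list(fm.labels) == list(df["group"])
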