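"""Windowing and the generic / actigraphy feature families."""

import numpy as np
import pandas as pd
import pytest

import beatpd.feature_extraction as fx
from beatpd.data_model_io import Segment


def make_segment(duration=1200.0, fs=10.0, value=1.0, mid="m1", **kwargs):
    n = int(duration * fs)
    t = np.arange(n) / fs
    df = pd.DataFrame({"t": t, "x": np.full(n, value), "y": np.zeros(n),
                       "z": np.zeros(n)})
    return Segment(mid, df, **kwargs)


def make_window(v, fs=50.0, t=None, width=30.0):
    v = np.asarray(v, dtype=float)
    t = np.arange(len(v)) / fs if t is None else t
    return fx.Window("m", 0, t, v, sampling_rate=fs, width=width)


def brute_force_peaks(v):
    """Oracle: sample strictly greater than both neighbours."""
    return sum(1 for i in range(1, len(v) - 1)
               if v[i] > v[i - 1] and v[i] > v[i + 1])


class TestCombineRms:
    @pytest.mark.parametrize("xyz,expected", [
        ((1, 0, 0), 1.0), ((1, 1, 1), np.sqrt(3)), ((0, 0, 0), 0.0)])
    def test_closed_forms(self, xyz, expected):
        x, y, z = ([v] for v in xyz)
        assert fx.combine_rms(x, y, z)[0] == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            fx.combine_rms([1, 2], [1], [1, 2])


class TestWindowing:
    def test_full_segment_gives_40_windows(self):
        assert len(fx.window_segment(make_segment(1200.0))) == 40

    def test_95s_segment_gives_3_windows(self):
        assert len(fx.window_segment(make_segment(95.0))) == 3

    def test_sparse_window_is_dropped(self):
        seg = make_segment(90.0, fs=10.0)
        # thin the middle window to 10% of expected samples
        t = seg.samples["t"]
        keep = ~((t >= 30) & (t < 60)) | (t % 10 < 0.3)
        seg = Segment("m1", seg.samples[keep].reset_index(drop=True))
        windows = fx.window_segment(seg, sampling_rate=10.0)
        assert [w.window_index for w in windows] == [0, 2]


class TestGenericFeatures:
    def test_constant_window_dc_only(self):
        c = 0.7
        w = make_window(np.full(300, c), fs=10.0)
        f = fx.generic_features(w)
        assert f["mean"] == pytest.approx(c)
        for q in (0.2, 0.3, 0.4, 0.7, 0.8):
            assert f[f"quantile_q_{q:.1f}"] == pytest.approx(c)
        assert f["number_peaks_n_1"] == 0
        assert f["spectral_entropy"] == 0
        assert f["fft_coefficient_0_real"] == pytest.approx(300 * c)

    def test_number_peaks_matches_brute_force(self, rng):
        assert fx.number_peaks(np.array([0, 1, 0, 1, 0.0]), 1) == 2
        for _ in range(20):
            v = rng.integers(0, 5, size=30).astype(float)
            assert fx.number_peaks(v, 1) == brute_force_peaks(v)

    def test_fft_dc_abs_equals_abs_sum(self, rng):
        v = rng.normal(1, 0.2, size=1500)
        f = fx.generic_features(make_window(v))
        assert f["fft_coefficient_0_abs"] == pytest.approx(abs(v.sum()),
                                                           rel=1e-9)

    def test_contains_the_named_top_features(self):
        needed = {"quantile_q_0.2", "quantile_q_0.3", "quantile_q_0.4",
                  "quantile_q_0.7", "quantile_q_0.8", "number_peaks_n_1",
                  "sum_values", "mean", "fft_coefficient_0_real",
                  "fft_coefficient_0_abs", "variance", "standard_deviation",
                  "minimum", "maximum", "median", "zero_crossings",
                  "band_power_0.5_3", "band_power_3_7", "band_power_7_12",
                  "spectral_entropy", "dominant_frequency"}
        assert needed <= set(fx.GENERIC_FEATURES)
        assert len(fx.GENERIC_FEATURES) >= 30

    def test_translation_equivariance_in_time(self, rng):
        v = rng.normal(1, 0.1, size=1500)
        t = np.arange(1500) / 50.0
        a = fx.generic_features(make_window(v, t=t))
        b = fx.generic_features(make_window(v, t=t + 137.5))
        assert a == b

    def test_adding_band_component_increases_band_power(self, rng):
        t = np.arange(1500) / 50.0
        base = rng.normal(1, 0.05, size=1500)
        bumped = base + 0.05 * np.sin(2 * np.pi * 5.0 * t)
        fa = fx.generic_features(make_window(base, t=t))
        fb = fx.generic_features(make_window(bumped, t=t))
        assert fb["band_power_3_7"] > fa["band_power_3_7"]

    def test_determinism(self, rng):
        v = rng.normal(1, 0.1, size=1500)
        assert fx.generic_features(make_window(v)) == \
            fx.generic_features(make_window(v.copy()))


class TestActigraphyFeatures:
    def triaxial(self, x, y, z, fs=50.0):
        data = np.column_stack([x, y, z])
        t = np.arange(len(x)) / fs
        return fx.Window("m", 0, t, data, sampling_rate=fs, width=30.0)

    def test_exactly_16_features(self, rng):
        w = self.triaxial(*(rng.normal(0, 1, (3, 1500))))
        f = fx.actigraphy_features(w)
        assert len(f) == 16
        assert set(f) == set(fx.ACTIGRAPHY_FEATURES)

    def test_pure_sinusoid_dominant_frequency(self):
        t = np.arange(1500) / 50.0
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 5.0 * t)
        f = fx.actigraphy_features(self.triaxial(x, np.zeros(1500),
                                                 np.zeros(1500)))
        assert f["dominant_frequency"] == pytest.approx(5.0, abs=1 / 30.0)

    def test_identical_axes_have_unit_correlation(self, rng):
        x = rng.normal(0, 1, 1500)
        f = fx.actigraphy_features(self.triaxial(x, x.copy(),
                                                 rng.normal(0, 1, 1500)))
        assert f["corr_xy"] == pytest.approx(1.0)

    def test_white_noise_axes_nearly_uncorrelated(self, rng):
        # |corr| < 0.1 holds with ~95% probability at n = 1500; seeded
        f = fx.actigraphy_features(self.triaxial(*rng.normal(0, 1, (3, 1500))))
        assert abs(f["corr_xy"]) < 0.1

    def test_zero_variance_axis_correlation_is_zero(self, rng):
        f = fx.actigraphy_features(self.triaxial(
            np.zeros(1500), rng.normal(0, 1, 1500), rng.normal(0, 1, 1500)))
        assert f["corr_xy"] == 0.0 and f["corr_xz"] == 0.0

    def test_cpm_scales_with_deviation_from_gravity(self):
        still = self.triaxial(np.zeros(1500), np.zeros(1500), np.ones(1500))
        t = np.arange(1500) / 50.0
        moving = self.triaxial(0.2 * np.sin(2 * np.pi * t), np.zeros(1500),
                               np.ones(1500))
        assert fx.actigraphy_features(still)["cpm"] == pytest.approx(0.0)
        assert fx.actigraphy_features(moving)["cpm"] > 0


class TestDesignMatrix:
    def covariates(self, subjects):
        rows = []
        for i, s in enumerate(subjects):
            row = {"subject_id": s, "cohort_id": "CIS", "age": 60 + i,
                   "gender": "F", "updrs_part1_total": 8,
                   "updrs_part2_total": 10, "mean_reporting_lag": 20.0}
            row.update({f"updrs_3_on_{j:02d}": 1 for j in range(1, 34)})
            row.update({f"updrs_3_off_{j:02d}": 2 for j in range(1, 34)})
            row.update({f"updrs_4_{j}": 1 for j in range(1, 7)})
            rows.append(row)
        return pd.DataFrame(rows)

    def features(self, n_obs=4, windows=2):
        rows = []
        for i in range(n_obs):
            for w in range(windows):
                rows.append({"measurement_id": f"S1-{i:04d}",
                             "subject_id": "S1", "window_index": w,
                             "device": "watch", "mean": 1.0 + i,
                             "variance": 0.1})
        return pd.DataFrame(rows)

    def labels(self, n_obs=4):
        return pd.DataFrame({
            "measurement_id": [f"S1-{i:04d}" for i in range(n_obs)],
            "subject_id": "S1", "cohort_id": "CIS",
            "on_off": 1.0, "dyskinesia": 0.0,
            "tremor": [float(i % 3) for i in range(n_obs)]})

    def test_sensor_only_keeps_feature_columns(self):
        df = fx.assemble_design_matrix(self.features(), self.labels(),
                                       mode="sensor_only")
        assert len(df) == 8
        assert "age" not in df.columns and "tremor" in df.columns

    def test_with_covariates_constant_within_subject(self):
        df = fx.assemble_design_matrix(self.features(), self.labels(),
                                       covariates=self.covariates(["S1"]),
                                       mode="with_covariates")
        for col in fx.COVARIATE_FEATURES:
            assert df[col].nunique() == 1

    def test_part3_pca_zero_for_identical_subjects(self):
        scores = fx.part3_pca_scores(self.covariates(["S1", "S2", "S3"]))
        assert np.allclose(scores, 0.0)

    def test_windows_inherit_observation_labels(self):
        df = fx.assemble_design_matrix(self.features(), self.labels(),
                                       mode="sensor_only")
        per_obs = df.groupby("measurement_id")["tremor"].nunique()
        assert (per_obs == 1).all()
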