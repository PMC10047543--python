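"""Simulator determinism, signal-label coupling and label statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy import stats

from beatpd.synthetic_cohort import (CohortSpec, ConfigurationError,
                                     generate_cohort, sample_labels,
                                     synthesize_segment)
from conftest import make_profile, quiet_spec


def band_power_3_7(seg, fs=50.0):
    """Independent band-power estimate via scipy's periodogram."""
    xyz = seg.samples[["x", "y", "z"]].to_numpy()
    vm = np.linalg.norm(xyz, axis=1)
    freqs, psd = sps.periodogram(vm - vm.mean(), fs=fs)
    mask = (freqs >= 3) & (freqs <= 7)
    return np.trapezoid(psd[mask], freqs[mask])


def synth(profile, tremor, dysk, off, spec, seed):
    labels = {"_tremor_h": tremor, "_dysk_h": dysk, "_off": off,
              "measurement_id": "m"}
    return synthesize_segment(profile, labels, spec,
                              np.random.default_rng(seed))


class TestDeterminismAndConfig:
    def test_identical_spec_and_seed_give_identical_datasets(self, tmp_path):
        spec = CohortSpec(cohort_id="CIS", n_subjects=3,
                          reports_per_subject_range=(6, 8),
                          segment_duration=30.0, seed=7)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.labels, b.labels)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            pd.testing.assert_frame_equal(sa.samples, sb.samples)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        fa = sorted((tmp_path / "a").rglob("*.csv"))
        fb = sorted((tmp_path / "b").rglob("*.csv"))
        assert [p.read_bytes() for p in fa] == [p.read_bytes() for p in fb]

    @pytest.mark.parametrize("bad", [
        dict(segment_duration=-5.0), dict(sampling_rate=0.0),
        dict(n_subjects=0), dict(onoff_attenuation=1.5),
        dict(tremor_coupling=-0.1), dict(missingness_rate=1.0),
        dict(cohort_id="OTHER"),
    ])
    def test_invalid_configuration_raises(self, bad):
        with pytest.raises(ConfigurationError):
            CohortSpec(**bad).validate()


class TestSignalSynthesis:
    def test_all_noise_sources_off_gives_constant_gravity(self, profile):
        seg = synth(profile, 0, 0, 0, quiet_spec(), seed=1)
        xyz = seg.samples[["x", "y", "z"]].to_numpy()
        assert np.allclose(xyz.var(axis=0), 0)
        assert np.allclose(np.linalg.norm(xyz, axis=1), 1.0)

    def test_tremor_4_has_more_band_power_than_tremor_0(self, profile):
        spec = quiet_spec(tremor_coupling=0.05, baseline_motion_sd=0.02)
        hi = synth(profile, 4, 0, 1, spec, seed=2)
        lo = synth(profile, 0, 0, 1, spec, seed=2)
        assert band_power_3_7(hi) > band_power_3_7(lo)

    def test_missingness_thins_samples_binomially(self, profile):
        spec = quiet_spec(segment_duration=1200.0, missingness_rate=0.1)
        seg = synth(profile, 0, 0, 0, spec, seed=3)
        n, p = 60000, 0.9
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(seg.samples) - n * p) < 5 * sd

    def test_onoff_attenuation_reduces_tremor_amplitude(self, profile):
        spec = quiet_spec(tremor_coupling=0.05, onoff_attenuation=0.3)
        on = synth(profile, 3, 0, 0, spec, seed=4)
        off = synth(profile, 3, 0, 1, spec, seed=4)
        assert band_power_3_7(off) > band_power_3_7(on)

    def test_dyskinesia_adds_low_band_noise(self, profile):
        spec = quiet_spec(dyskinesia_coupling=0.02)
        seg = synth(profile, 0, 3, 0, spec, seed=5)
        none = synth(profile, 0, 0, 0, spec, seed=5)
        xyz = seg.samples[["x", "y", "z"]].to_numpy()
        assert xyz.var(axis=0).sum() > 1e-6
        assert np.allclose(
            none.samples[["x", "y", "z"]].to_numpy().var(axis=0), 0)


class TestLabelSampling:
    def test_degenerate_distribution_gives_constant_labels(self, rng):
        p = make_profile(theta={"tremor": 2.0, "dyskinesia": 1.0,
                                "on_off": 2.0},
                         label_sd={"tremor": 0.0, "dyskinesia": 0.0,
                                   "on_off": 0.0})
        labels = sample_labels(p, 30, rng)
        assert (labels["tremor"] == 2).all()

    def test_n_reports_records_with_nonnegative_lags(self, rng):
        labels = sample_labels(make_profile(), 50, rng)
        assert len(labels) == 50
        lags = labels["timestamp_report"] - labels["timestamp_slot"]
        assert (lags >= 0).all()

    def test_slots_spaced_at_least_30_minutes(self, rng):
        labels = sample_labels(make_profile(), 40, rng)
        assert np.diff(labels["timestamp_slot"]).min() >= 1800

    def test_label_mean_matches_clipped_rounded_gaussian(self, rng):
        # closed-form oracle: P(label = k) from the normal CDF over the
        # rounding cells, clipped at the scale ends
        theta, sd, n = 2.0, 1.0, 500
        p = make_profile(theta={"tremor": theta, "dyskinesia": 1.0,
                                "on_off": 2.0},
                         label_sd={"tremor": sd, "dyskinesia": 0.5,
                                   "on_off": 0.5})
        probs = []
        for k in range(5):
            lo = -np.inf if k == 0 else (k - 0.5 - theta) / sd
            hi = np.inf if k == 4 else (k + 0.5 - theta) / sd
            probs.append(stats.norm.cdf(hi) - stats.norm.cdf(lo))
        mean_expected = sum(k * q for k, q in enumerate(probs))
        var_expected = sum(k * k * q for k, q in enumerate(probs)) \
            - mean_expected ** 2
        labels = sample_labels(p, n, rng)
        se = np.sqrt(var_expected / n)
        assert abs(labels["tremor"].mean() - mean_expected) < 2 * se

    def test_real_labels_on_native_scales(self, rng):
        p = make_profile(subject_id="REAL000", cohort_id="REAL")
        labels = sample_labels(p, 60, rng)
        assert labels["tremor"].between(1, 5).all()
        cats = set(labels["on_off"])
        assert cats <= {"OFF", "ON without dyskinesia",
                        "ON with non-troublesome dyskinesia",
                        "ON with severe dyskinesia"}
        assert labels["dyskinesia"].isna().all()

    def test_emitted_labels_lie_in_native_range(self):
        for cid in ("CIS", "REAL"):
            spec = CohortSpec(cohort_id=cid, n_subjects=2,
                              reports_per_subject_range=(30, 30),
                              segment_duration=30.0, seed=11)
            cohort = generate_cohort(spec)
            if cid == "CIS":
                for col in ("on_off", "dyskinesia", "tremor"):
                    assert cohort.labels[col].between(0, 4).all()
            else:
                assert cohort.labels["tremor"].between(1, 5).all()


class TestCoupling:
    def _label_band_powers(self, kappa_t, n_per_label=40, seed=0):
        spec = quiet_spec(tremor_coupling=kappa_t, baseline_motion_sd=0.02,
                          sensor_noise_sd=0.005, segment_duration=60.0)
        profile = make_profile()
        rng = np.random.default_rng(seed)
        powers, labels = [], []
        for label in range(5):
            for _ in range(n_per_label):
                seg = synthesize_segment(
                    profile, {"_tremor_h": label, "_dysk_h": 0, "_off": 1,
                              "measurement_id": "m"}, spec, rng)
                powers.append(band_power_3_7(seg))
                labels.append(label)
        return np.array(labels), np.array(powers)

    def test_band_power_strictly_increases_with_tremor_label(self):
        labels, powers = self._label_band_powers(0.05)
        means = [powers[labels == k].mean() for k in range(5)]
        assert all(means[k] < means[k + 1] for k in range(4))

    def test_zero_coupling_gives_no_label_power_correlation(self):
        labels, powers = self._label_band_powers(0.0)
        r = np.corrcoef(labels, powers)[0, 1]
        assert abs(r) < 0.15

    def test_null_coupling_mutual_information_indistinguishable_from_zero(self):
        labels, powers = self._label_band_powers(0.0, n_per_label=40, seed=1)

        def mi(y, f):
            bins = np.quantile(f, np.linspace(0, 1, 6))
            fb = np.clip(np.digitize(f, bins[1:-1]), 0, 4)
            joint = np.zeros((5, 5))
            for a, b in zip(y.astype(int), fb):
                joint[a, b] += 1
            joint /= joint.sum()
            px, py = joint.sum(1, keepdims=True), joint.sum(0, keepdims=True)
            nz = joint > 0
            return float((joint[nz] * np.log(joint[nz]
                                             / (px @ py)[nz])).sum())

        observed = mi(labels, powers)
        rng = np.random.default_rng(2)
        perms = [mi(rng.permutation(labels), powers) for _ in range(199)]
        p = (1 + sum(v >= observed for v in perms)) / 200
        assert p > 0.01
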