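"""Synthetic free-living smartwatch cohorts.

Generates two-cohort datasets with the statistical structure the
challenge data possessed, so the full pipeline is testable without the
access-controlled study data: per-subject collections of non-overlapping
20-minute triaxial accelerometer segments, each paired with a diary
report of medication state, dyskinesia and tremor on the cohorts'
native scales, plus demographics and MDS-UPDRS covariates.

Signal model per segment (all amplitudes in g):

* gravity: a ~1 g vector whose orientation performs a slow random walk;
* baseline motion: band-limited (0.5-8 Hz) Gaussian noise, sd ``sigma_b``;
* tremor: a narrowband sinusoid at a per-subject frequency drawn once
  from U(4, 6) Hz with random-walk phase, amplitude
  ``kappa_T * tremor * (gamma if ON else 1)`` along a fixed per-subject
  direction;
* dyskinesia: 1-3 Hz band-filtered noise with sd ``kappa_D * dyskinesia``;
* white sensor noise, sd ``sigma_n``; a fraction ``missingness_rate`` of
  samples is deleted at random.

Medication state alternates in daily ON/OFF cycles and attenuates the
tremor amplitude by ``gamma`` while ON, which is what makes the on/off
label learnable from the sensor stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import (LABEL_RANGES, REAL_MEDICATION_MAP, Segment,
                            write_labels, write_segment)

logger = logging.getLogger("beatpd")

_REAL_CATEGORY_BY_DYSK = {0: "ON without dyskinesia",
                          1: "ON with non-troublesome dyskinesia",
                          3: "ON with severe dyskinesia"}


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class CohortSpec:
    """Free parameters of the cohort simulator.

    Couplings are in g per harmonized severity unit; ``onoff_attenuation``
    multiplies the tremor amplitude while the patient is ON (medication
    effective), so values below one make the medication state visible in
    the 3-7 Hz band.
    """

    cohort_id: str = "CIS"
    n_subjects: int = 10
    reports_per_subject_range: tuple[int, int] = (50, 70)
    sampling_rate: float = 50.0  # Hz
    segment_duration: float = 1200.0  # seconds
    tremor_coupling: float = 0.05  # kappa_T, g per severity unit
    dyskinesia_coupling: float = 0.005  # kappa_D
    onoff_attenuation: float = 0.5  # gamma, in [0, 1]
    baseline_motion_sd: float = 0.02  # sigma_b
    activity_variability: float = 0.5  # sd of log activity scale per segment
    sensor_noise_sd: float = 0.005  # sigma_n
    missingness_rate: float = 0.02
    orientation_drift_sd: float = 0.01  # rad per sqrt(second)
    second_device_rate: float = 0.0  # REAL: fraction of reports with a phone stream
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_id not in ("CIS", "REAL"):
            raise ConfigurationError(f"unknown cohort_id {self.cohort_id!r}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_rate <= 0 or self.segment_duration <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        lo, hi = self.reports_per_subject_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("invalid reports_per_subject_range")
        for name in ("tremor_coupling", "dyskinesia_coupling",
                     "baseline_motion_sd", "sensor_noise_sd",
                     "activity_variability"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.onoff_attenuation <= 1:
            raise ConfigurationError("onoff_attenuation must be in [0, 1]")
        if not 0 <= self.missingness_rate < 1:
            raise ConfigurationError("missingness_rate must be in [0, 1)")


@dataclass
class SubjectProfile:
    """Per-subject latent severities, variability and MDS-UPDRS covariates."""

    subject_id: str
    cohort_id: str
    age: int
    gender: str
    updrs_part1_total: int
    updrs_part2_total: int
    updrs_part3_items_on: np.ndarray  # 33 items, 0-4
    updrs_part3_items_off: np.ndarray
    updrs_part4_items: np.ndarray  # 6 items, 0-4
    mean_severity: dict  # symptom -> theta_s (harmonized scale)
    label_sd: dict  # symptom -> sd of the latent report
    mean_reporting_lag: float  # minutes
    tremor_frequency: float = 5.0  # Hz, drawn once per subject from U(4, 6)
    tremor_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    onoff_phase: float = 0.0  # seconds, offset of the daily medication cycle
    coupling_scale: float = 1.0  # per-subject multiplier on both couplings


@dataclass
class SyntheticCohort:
    """Output of :func:`generate_cohort`."""

    spec: CohortSpec
    profiles: list[SubjectProfile]
    labels: pd.DataFrame  # native-scale public label table
    segments: list[Segment]

    def covariates(self) -> pd.DataFrame:
        return covariates_table(self.profiles)

    def write(self, outdir: str | Path) -> None:
        """Emit the on-disk formats the readers consume."""
        outdir = Path(outdir)
        seg_dir = outdir / "segments"
        seg_dir.mkdir(parents=True, exist_ok=True)
        for seg in self.segments:
            suffix = "" if seg.device == "watch" else f"_{seg.device}"
            write_segment(seg, seg_dir / f"{seg.measurement_id}{suffix}.csv")
        public = self.labels[[c for c in self.labels.columns
                              if not c.startswith("_")]]
        write_labels(public, outdir / f"labels_{self.spec.cohort_id}.csv")
        write_labels(self.covariates(),
                     outdir / f"covariates_{self.spec.cohort_id}.csv")


# ---------------------------------------------------------------------------
# Band-limited noise helper
# ---------------------------------------------------------------------------

def band_noise(n: int, fs: float, lo: float, hi: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with spectral support restricted to [lo, hi] Hz."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _generate_profile(spec: CohortSpec, index: int,
                      rng: np.random.Generator) -> SubjectProfile:
    subject_id = f"{spec.cohort_id}{index:03d}"
    # Latent mean severities on the harmonized scales.
    theta = {
        "tremor": float(rng.uniform(0.5, 3.5)),
        "dyskinesia": float(rng.uniform(0.3, 2.7)),
        "on_off": float(rng.uniform(1.0, 4.0)),  # CIS off-severity scale
    }
    label_sd = {s: float(rng.uniform(0.4, 1.0)) for s in theta}
    # Overall disease severity in [0, 1] drives the UPDRS covariates so that
    # totals correlate positively with the latent symptom severities.
    sev = (theta["tremor"] / 4 + theta["dyskinesia"] / 3
           + theta["on_off"] / 4) / 3
    p3_mean_on = 0.5 + 2.5 * sev
    items_on = np.clip(np.round(rng.normal(p3_mean_on, 0.7, size=33)),
                       0, 4).astype(int)
    items_off = np.clip(items_on + rng.integers(0, 2, size=33), 0, 4).astype(int)
    p4 = np.clip(np.round(rng.normal(0.5 + 2.0 * theta["dyskinesia"] / 3,
                                     0.7, size=6)), 0, 4).astype(int)
    return SubjectProfile(
        subject_id=subject_id,
        cohort_id=spec.cohort_id,
        age=int(rng.integers(45, 85)),
        gender=str(rng.choice(["F", "M"])),
        updrs_part1_total=int(np.clip(round(rng.normal(8 + 10 * sev, 3)), 0, 52)),
        updrs_part2_total=int(np.clip(round(rng.normal(10 + 14 * sev, 3)), 0, 52)),
        updrs_part3_items_on=items_on,
        updrs_part3_items_off=items_off,
        updrs_part4_items=p4,
        mean_severity=theta,
        label_sd=label_sd,
        mean_reporting_lag=float(rng.uniform(5.0, 60.0)),
        tremor_frequency=float(rng.uniform(4.0, 6.0)),
        tremor_direction=_tremor_direction(rng),
        onoff_phase=float(rng.uniform(0, 4 * 3600)),
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _tremor_direction(rng: np.random.Generator) -> np.ndarray:
    """Tremor direction with a guaranteed vertical (gravity-aligned)
    component.

    Wrist tremor rotates the watch, so the projection of gravity onto the
    sensor axes oscillates at the tremor frequency; a minimum vertical
    component makes that rotational effect visible in the vector
    magnitude, where the feature extractors look for it.
    """
    z = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
    psi = rng.uniform(0, 2 * np.pi)
    h = np.sqrt(1 - z ** 2)
    return np.array([h * np.cos(psi), h * np.sin(psi), z])


def covariates_table(profiles: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "cohort_id": p.cohort_id,
            "age": p.age,
            "gender": p.gender,
            "updrs_part1_total": p.updrs_part1_total,
            "updrs_part2_total": p.updrs_part2_total,
            "mean_reporting_lag": p.mean_reporting_lag,
        }
        for i, v in enumerate(p.updrs_part3_items_on, start=1):
            row[f"updrs_3_on_{i:02d}"] = int(v)
        for i, v in enumerate(p.updrs_part3_items_off, start=1):
            row[f"updrs_3_off_{i:02d}"] = int(v)
        for i, v in enumerate(p.updrs_part4_items, start=1):
            row[f"updrs_4_{i}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def _off_state(slot_time: float, phase: float, cycle: float = 4 * 3600) -> bool:
    """Daily medication cycle: alternating ON/OFF blocks of cycle/2 seconds."""
    return ((slot_time + phase) % cycle) >= cycle / 2


def sample_labels(profile: SubjectProfile, n_reports: int,
                  rng: np.random.Generator,
                  spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a subject's diary: native-scale labels, slots, reporting lags.

    Each symptom label is ``round(theta_s + N(0, label_sd))`` clipped to
    its native range; medication state alternates in daily cycles; the
    reporting lag is exponential with the subject's mean.  Report slots
    are spaced at least 30 minutes apart.  Columns prefixed ``_`` are
    internal harmonized values used by the signal synthesiser and are
    not written to the public label files.
    """
    if n_reports < 1:
        raise ConfigurationError("n_reports must be >= 1")
    cohort = profile.cohort_id
    # >=30-minute spacing: 30 min plus a random non-negative gap.
    gaps = 1800.0 + rng.exponential(900.0, size=n_reports)
    slots = np.cumsum(gaps) - gaps[0]
    lags_min = rng.exponential(profile.mean_reporting_lag, size=n_reports)

    def draw(symptom: str, lo: int, hi: int) -> np.ndarray:
        raw = np.round(profile.mean_severity[symptom]
                       + rng.normal(0, profile.label_sd[symptom],
                                    size=n_reports))
        clipped = np.clip(raw, lo, hi) + 0.0
        clipped[clipped == 0] = 0.0  # normalise -0.0
        if (raw != clipped).any():
            logger.debug("clipped %d %s labels of %s to [%d, %d]",
                         int((raw != clipped).sum()), symptom,
                         profile.subject_id, lo, hi)
        return clipped

    tremor_h = draw("tremor", 0, 4)
    off = np.array([_off_state(s, profile.onoff_phase) for s in slots])
    rows: dict = {
        "measurement_id": [f"{profile.subject_id}-{k:04d}"
                           for k in range(n_reports)],
        "subject_id": profile.subject_id,
        "timestamp_slot": slots,
        "timestamp_report": slots + lags_min * 60.0,
    }
    if cohort == "CIS":
        dysk_h = draw("dyskinesia", 0, 4)
        onoff_label = np.clip(
            np.round(profile.mean_severity["on_off"] * off.astype(float)
                     + rng.normal(0, profile.label_sd["on_off"],
                                  size=n_reports)), 0, 4)
        onoff_label[onoff_label == 0] = 0.0  # normalise -0.0
        rows.update(on_off=onoff_label, dyskinesia=dysk_h, tremor=tremor_h)
    else:
        dysk_latent = draw("dyskinesia", 0, 3)
        # REAL dyskinesia is reported through the 4-category medication
        # diary: zero while OFF, else snapped to the representable levels.
        dysk_h = np.where(off, 0.0,
                          np.array([min((0, 1, 3), key=lambda c: abs(c - d))
                                    for d in dysk_latent], dtype=float))
        med = np.where(off, "OFF",
                       [_REAL_CATEGORY_BY_DYSK[int(d)] for d in dysk_h])
        rows.update(on_off=med, dyskinesia=np.nan, tremor=tremor_h + 1.0)
    rows.update(_tremor_h=tremor_h, _dysk_h=dysk_h, _off=off.astype(int))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def synthesize_segment(profile: SubjectProfile, labels: pd.Series | dict,
                       spec: CohortSpec, rng: np.random.Generator,
                       measurement_id: str | None = None,
                       device: str = "watch") -> Segment:
    """Render one triaxial segment for a single diary report.

    ``labels`` must carry the internal harmonized fields ``_tremor_h``,
    ``_dysk_h`` and ``_off`` produced by :func:`sample_labels`.
    """
    spec.validate()
    fs = spec.sampling_rate
    n = int(round(spec.segment_duration * fs))
    t = np.arange(n) / fs

    tremor_h = float(np.clip(labels["_tremor_h"], 0, 4))
    dysk_h = float(np.clip(labels["_dysk_h"], 0, 4))
    off = bool(labels["_off"])
    scale = profile.coupling_scale

    # Gravity with slow orientation drift (random-walk pitch/roll).
    if spec.orientation_drift_sd > 0:
        step = spec.orientation_drift_sd / np.sqrt(fs)
        pitch = np.cumsum(rng.normal(0, step, size=n))
        roll = np.cumsum(rng.normal(0, step, size=n))
    else:
        pitch = np.zeros(n)
        roll = np.zeros(n)
    grav = np.empty((n, 3))
    grav[:, 0] = np.sin(pitch)
    grav[:, 1] = -np.sin(roll) * np.cos(pitch)
    grav[:, 2] = np.cos(roll) * np.cos(pitch)

    xyz = grav
    if spec.baseline_motion_sd > 0:
        # Free-living voluntary activity varies strongly between segments;
        # a per-segment log-normal scale on the baseline motion creates the
        # broadband background against which dyskinesia (gross motion in
        # the same low band) is genuinely hard to separate, while the
        # narrowband tremor peak remains detectable.
        scale_b = float(np.exp(rng.normal(0.0, spec.activity_variability))) \
            if spec.activity_variability > 0 else 1.0
        for ax in range(3):
            xyz[:, ax] += band_noise(n, fs, 0.5, 8.0,
                                     spec.baseline_motion_sd * scale_b, rng)
    amp = scale * spec.tremor_coupling * tremor_h * (
        1.0 if off else spec.onoff_attenuation)
    if amp > 0:
        phase = 2 * np.pi * profile.tremor_frequency * t \
            + np.cumsum(rng.normal(0, 0.05, size=n))
        xyz += amp * np.sin(phase)[:, None] * profile.tremor_direction[None, :]
    dysk_sd = scale * spec.dyskinesia_coupling * dysk_h
    if dysk_sd > 0:
        for ax in range(3):
            xyz[:, ax] += band_noise(n, fs, 1.0, 3.0, dysk_sd, rng)
    if spec.sensor_noise_sd > 0:
        xyz += rng.normal(0, spec.sensor_noise_sd, size=(n, 3))
    if spec.missingness_rate > 0:
        keep = rng.random(n) >= spec.missingness_rate
        t, xyz = t[keep], xyz[keep]

    mid = measurement_id or str(labels.get("measurement_id", "segment"))
    samples = pd.DataFrame({"t": t, "x": xyz[:, 0], "y": xyz[:, 1],
                            "z": xyz[:, 2]})
    return Segment(mid, samples, subject_id=profile.subject_id,
                   cohort_id=profile.cohort_id, device=device)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec,
                    profile_overrides: dict | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort deterministically from the spec.

    ``profile_overrides`` optionally maps a profile field name to a
    sequence of per-subject values (e.g. per-subject ``coupling_scale``),
    applied after profiles are drawn.
    """
    spec.validate()
    root = np.random.SeedSequence([spec.seed, 0 if spec.cohort_id == "CIS" else 1])
    ss_profiles, ss_subjects = root.spawn(2)
    prof_rng = np.random.default_rng(ss_profiles)
    profiles = [_generate_profile(spec, i, prof_rng)
                for i in range(spec.n_subjects)]
    if profile_overrides:
        for name, values in profile_overrides.items():
            for p, v in zip(profiles, values):
                setattr(p, name, v)

    lo, hi = spec.reports_per_subject_range
    all_labels = []
    segments: list[Segment] = []
    for p, ss in zip(profiles, ss_subjects.spawn(spec.n_subjects)):
        rng = np.random.default_rng(ss)
        n_reports = int(rng.integers(lo, hi + 1))
        labels = sample_labels(p, n_reports, rng, spec)
        for _, row in labels.iterrows():
            segments.append(synthesize_segment(p, row, spec, rng,
                                               measurement_id=row["measurement_id"]))
            if (spec.cohort_id == "REAL" and spec.second_device_rate > 0
                    and rng.random() < spec.second_device_rate):
                segments.append(synthesize_segment(
                    p, row, spec, rng,
                    measurement_id=str(row["measurement_id"]),
                    device="phone"))
        all_labels.append(labels)
    label_table = pd.concat(all_labels, ignore_index=True)
    return SyntheticCohort(spec=spec, profiles=profiles, labels=label_table,
                           segments=segments)
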