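import numpy as np
import pandas as pd
import pytest

from beatpd.synthetic_cohort import CohortSpec, SubjectProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(subject_id="CIS000", cohort_id="CIS", theta=None,
                 label_sd=None, **kwargs) -> SubjectProfile:
    theta = theta or {"tremor": 2.0, "dyskinesia": 1.0, "on_off": 2.0}
    label_sd = label_sd or {s: 0.6 for s in theta}
    defaults = dict(
        subject_id=subject_id, cohort_id=cohort_id, age=65, gender="F",
        updrs_part1_total=10, updrs_part2_total=12,
        updrs_part3_items_on=np.ones(33, dtype=int),
        updrs_part3_items_off=np.full(33, 2, dtype=int),
        updrs_part4_items=np.ones(6, dtype=int),
        mean_severity=theta, label_sd=label_sd, mean_reporting_lag=20.0,
        tremor_frequency=5.0,
        tremor_direction=np.array([0.6, 0.0, 0.8]),
        onoff_phase=0.0,
    )
    defaults.update(kwargs)
    return SubjectProfile(**defaults)


@pytest.fixture
def profile():
    return make_profile()


def quiet_spec(**kwargs) -> CohortSpec:
    """A spec with every stochastic signal component switched off."""
    defaults = dict(cohort_id="CIS", n_subjects=1,
                    reports_per_subject_range=(5, 5), sampling_rate=50.0,
                    segment_duration=30.0, tremor_coupling=0.0,
                    dyskinesia_coupling=0.0, onoff_attenuation=1.0,
                    baseline_motion_sd=0.0, activity_variability=0.0,
                    sensor_noise_sd=0.0, missingness_rate=0.0,
                    orientation_drift_sd=0.0, seed=0)
    defaults.update(kwargs)
    return CohortSpec(**defaults)


def toy_labels(counts: dict, subject_id="S1", symptom="tremor",
               start=0) -> pd.DataFrame:
    """Build a label table with the given per-category counts."""
    rows = []
    i = start
    for value, n in counts.items():
        for _ in range(n):
            rows.append({"measurement_id": f"{subject_id}-{i:04d}",
                         "subject_id": subject_id, symptom: value})
            i += 1
    return pd.DataFrame(rows)
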