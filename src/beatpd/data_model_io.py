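"""Dataset formats and challenge data-preparation rules.

Covers reading/writing per-segment accelerometer CSVs and cohort label
tables, harmonization of the two cohorts' native label scales onto a
common one, the two-minute activity filter, per-symptom subject
eligibility, and the stratified within-subject 75/25 train/test split.

Conventions: timestamps are seconds as floats, zero-based at segment
start; time windows are half-open ``[a, b)``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("beatpd")

SYMPTOMS = ("on_off", "dyskinesia", "tremor")

#: Inclusive harmonized label range per (cohort, symptom).
LABEL_RANGES = {
    ("CIS", "on_off"): (0, 4),
    ("CIS", "dyskinesia"): (0, 4),
    ("CIS", "tremor"): (0, 4),
    ("REAL", "on_off"): (0, 1),
    ("REAL", "dyskinesia"): (0, 3),
    ("REAL", "tremor"): (0, 4),
}

#: REAL-PD four-category medication diary entries, mapped to
#: (on_off, dyskinesia) harmonized codes.  0 = ON, 1 = OFF so that larger
#: values always mean greater symptom burden.  The "severe" category maps
#: to dyskinesia level 3; level 2 is unused by construction.
REAL_MEDICATION_MAP = {
    "OFF": (1, 0),
    "ON without dyskinesia": (0, 0),
    "ON with non-troublesome dyskinesia": (0, 1),
    "ON with severe dyskinesia": (0, 3),
}


class FormatError(ValueError):
    """Raised when a data file violates the documented format."""


class HarmonizationError(ValueError):
    """Raised when a native label value is outside its cohort scale."""


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One sensor recording tied to a single diary report.

    ``samples`` is a DataFrame with columns ``t, x, y, z``: time in
    seconds from segment start and triaxial acceleration in g.
    """

    measurement_id: str
    samples: pd.DataFrame
    subject_id: str = ""
    cohort_id: str = ""
    device: str = "watch"

    def __post_init__(self) -> None:
        t = np.asarray(self.samples["t"], dtype=float)
        if len(t) and t[0] < 0:
            raise FormatError(f"{self.measurement_id}: negative start time {t[0]}")
        if len(t) > 1:
            bad = np.nonzero(np.diff(t) < 0)[0]
            if bad.size:
                row = int(bad[0]) + 1
                raise FormatError(
                    f"{self.measurement_id}: non-monotone t at row {row}"
                )

    @property
    def duration(self) -> float:
        t = self.samples["t"].to_numpy()
        return float(t[-1] - t[0]) if len(t) else 0.0

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(t, xyz)`` as float arrays; ``xyz`` is ``(n, 3)``."""
        t = self.samples["t"].to_numpy(dtype=float)
        xyz = self.samples[["x", "y", "z"]].to_numpy(dtype=float)
        return t, xyz


@dataclass
class LabelRecord:
    """Harmonized diary report for one measurement."""

    measurement_id: str
    subject_id: str
    cohort_id: str
    on_off: float
    dyskinesia: float
    tremor: float
    reporting_lag: float = np.nan  # minutes


@dataclass
class SplitAssignment:
    """Within-subject train/test partition shared across symptoms."""

    assignment: pd.DataFrame  # measurement_id, subject_id, partition
    seed: int = 0

    def partition_of(self, measurement_id: str) -> str:
        row = self.assignment.loc[
            self.assignment["measurement_id"] == measurement_id, "partition"
        ]
        return str(row.iloc[0])

    def test_counts(self) -> pd.Series:
        """Per-subject test observation counts ``n_k``."""
        test = self.assignment[self.assignment["partition"] == "test"]
        return test.groupby("subject_id")["measurement_id"].count()

    def ids(self, partition: str) -> list[str]:
        sel = self.assignment["partition"] == partition
        return self.assignment.loc[sel, "measurement_id"].tolist()


# ---------------------------------------------------------------------------
# Segment I/O
# ---------------------------------------------------------------------------

def read_segment(path: str | Path, subject_id: str = "", cohort_id: str = "",
                 device: str = "watch") -> Segment:
    """Read a per-segment CSV ``t,x,y,z`` (measurement id = file stem)."""
    path = Path(path)
    raw = path.read_bytes()
    if not raw.strip():
        raise FormatError(f"{path}: empty file")
    text = raw.decode("utf-8-sig")  # tolerate BOM; pandas handles CRLF
    df = pd.read_csv(io.StringIO(text))
    missing = [c for c in ("t", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    try:
        df = df[["t", "x", "y", "z"]].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value ({exc})") from exc
    try:
        return Segment(path.stem, df, subject_id=subject_id,
                       cohort_id=cohort_id, device=device)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_segment(segment: Segment, path: str | Path) -> None:
    """Write a segment CSV; round-trips losslessly at float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    segment.samples.to_csv(path, index=False, float_format="%.6f")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a cohort label table (native or harmonized scales)."""
    df = pd.read_csv(path, encoding="utf-8-sig")
    if "measurement_id" not in df.columns:
        raise FormatError(f"{path}: missing measurement_id column")
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _check_range(value: float, lo: int, hi: int, what: str) -> float:
    if np.isnan(value):
        return value
    if not lo <= value <= hi:
        raise HarmonizationError(f"{what}={value} outside [{lo}, {hi}]")
    return float(value)


def harmonize_labels(cohort_id: str, record: Mapping) -> LabelRecord:
    """Map one raw diary record onto the harmonized label scales.

    CIS records are already on the common 0-4 scales and pass through.
    REAL tremor is rescaled 1-5 -> 0-4 by subtracting one, and the
    four-category medication entry becomes binary ``on_off`` plus a
    0-3 ``dyskinesia`` level.  A record that already carries harmonized
    fields (numeric ``on_off``, no medication category) passes through,
    making the operation idempotent.
    """
    rec = dict(record)
    lag = float(rec.get("reporting_lag", np.nan))
    common = dict(
        measurement_id=str(rec.get("measurement_id", "")),
        subject_id=str(rec.get("subject_id", "")),
        cohort_id=cohort_id,
        reporting_lag=lag,
    )
    if cohort_id == "CIS":
        return LabelRecord(
            on_off=_check_range(float(rec.get("on_off", np.nan)), 0, 4, "on_off"),
            dyskinesia=_check_range(
                float(rec.get("dyskinesia", np.nan)), 0, 4, "dyskinesia"),
            tremor=_check_range(float(rec.get("tremor", np.nan)), 0, 4, "tremor"),
            **common,
        )
    if cohort_id != "REAL":
        raise HarmonizationError(f"unknown cohort {cohort_id!r}")

    med = rec.get("on_off", np.nan)
    if isinstance(med, str):
        if med not in REAL_MEDICATION_MAP:
            raise HarmonizationError(f"unknown medication category {med!r}")
        on_off, dysk = REAL_MEDICATION_MAP[med]
        on_off = float(on_off)
        dysk = float(dysk)
        tremor_native = float(rec.get("tremor", np.nan))
        if not np.isnan(tremor_native):
            _check_range(tremor_native, 1, 5, "tremor (native)")
            tremor = tremor_native - 1.0
        else:
            tremor = np.nan
    else:
        # Already harmonized: validate and pass through.
        on_off = _check_range(float(med), 0, 1, "on_off")
        dysk = _check_range(float(rec.get("dyskinesia", np.nan)), 0, 3,
                            "dyskinesia")
        tremor = _check_range(float(rec.get("tremor", np.nan)), 0, 4, "tremor")
    return LabelRecord(on_off=on_off, dyskinesia=dysk, tremor=tremor, **common)


def harmonize_table(cohort_id: str, df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`harmonize_labels` over a cohort label table."""
    records = [harmonize_labels(cohort_id, row)
               for row in df.to_dict(orient="records")]
    out = pd.DataFrame([vars(r) for r in records])
    keep = [c for c in df.columns if c not in out.columns]
    return pd.concat([out, df[keep].reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def activity_duration(segment: Segment, criterion: str = "presence",
                      motion_sd_threshold: float = 0.01) -> int:
    """Seconds of activity in a segment.

    Default criterion counts 1-second epochs containing at least one
    sample.  ``criterion="motion"`` additionally requires the epoch's
    vector-magnitude SD to exceed ``motion_sd_threshold`` (g).
    """
    t, xyz = segment.arrays()
    if len(t) == 0:
        return 0
    epochs = np.floor(t).astype(np.int64)
    if criterion == "presence":
        return int(np.unique(epochs).size)
    if criterion != "motion":
        raise ValueError(f"unknown activity criterion {criterion!r}")
    vm = np.sqrt((xyz ** 2).sum(axis=1))
    active = 0
    for _, idx in pd.Series(np.arange(len(t))).groupby(epochs):
        seg = vm[idx.to_numpy()]
        if len(seg) > 1 and seg.std() > motion_sd_threshold:
            active += 1
    return active


def filter_segments(segments: Iterable[Segment], min_active_seconds: int = 120,
                    criterion: str = "presence") -> list[Segment]:
    """Drop segments with less than two minutes of activity (inclusive bound)."""
    kept = []
    for seg in segments:
        if activity_duration(seg, criterion=criterion) >= min_active_seconds:
            kept.append(seg)
        else:
            logger.info("activity filter removed segment %s", seg.measurement_id)
    return kept


def filter_subjects(labels: pd.DataFrame, symptom: str,
                    min_observations: int = 40) -> set[str]:
    """Subjects eligible for a symptom's subchallenge.

    A subject qualifies with at least 40 non-missing observations and
    either >=2 label categories of >=10 observations each or >=3
    categories of >=5 each.
    """
    if symptom not in SYMPTOMS:
        raise ValueError(f"unknown symptom {symptom!r}")
    eligible: set[str] = set()
    for subject, grp in labels.groupby("subject_id"):
        values = grp[symptom].dropna()
        if len(values) < min_observations:
            continue
        counts = values.value_counts()
        if (counts >= 10).sum() >= 2 or (counts >= 5).sum() >= 3:
            eligible.add(str(subject))
    return eligible


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(labels: pd.DataFrame, ratio: float = 0.75,
                     seed: int = 0) -> SplitAssignment:
    """Within-subject stratified split shared across the three symptoms.

    Stratification is on the joint label tuple (missing values form
    their own stratum).  The per-subject test count is
    ``round(n * (1 - ratio))`` (half rounds up); stratum test counts are
    apportioned by largest remainder.  Strata of size one go to train.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    key_cols = [s for s in SYMPTOMS if s in labels.columns]
    df = labels.copy()
    df["_stratum"] = [
        tuple("NA" if pd.isna(v) else v for v in tup)
        for tup in df[key_cols].itertuples(index=False, name=None)
    ]
    for subject in sorted(df["subject_id"].astype(str).unique()):
        grp = df[df["subject_id"].astype(str) == subject]
        n_test_target = _round_half_up(len(grp) * (1 - ratio))
        strata = sorted(grp["_stratum"].unique(), key=repr)
        ideal = {s: (grp["_stratum"] == s).sum() * (1 - ratio) for s in strata}
        base = {s: int(np.floor(ideal[s])) for s in strata}
        # size-1 strata always train
        for s in strata:
            if (grp["_stratum"] == s).sum() == 1:
                base[s] = 0
                ideal[s] = 0.0
                logger.info("split: singleton stratum %r of subject %s -> train",
                            s, subject)
        deficit = n_test_target - sum(base.values())
        if deficit > 0:
            order = sorted(strata, key=lambda s: (-(ideal[s] - base[s]), repr(s)))
            order = [s for s in order
                     if (grp["_stratum"] == s).sum() > base[s]
                     and (grp["_stratum"] == s).sum() > 1]
            for s in order[:deficit]:
                base[s] += 1
        elif deficit < 0:
            order = sorted(strata, key=lambda s: ((ideal[s] - base[s]), repr(s)))
            order = [s for s in order if base[s] > 0]
            for s in order[:-deficit]:
                base[s] -= 1
        for s in strata:
            ids = grp.loc[grp["_stratum"] == s, "measurement_id"].tolist()
            test_ids = set(rng.choice(ids, size=min(base[s], len(ids)),
                                      replace=False)) if base[s] else set()
            for mid in ids:
                rows.append((mid, subject,
                             "test" if mid in test_ids else "train"))
    out = pd.DataFrame(rows, columns=["measurement_id", "subject_id",
                                      "partition"])
    return SplitAssignment(assignment=out, seed=seed)


def write_split(split: SplitAssignment, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    split.assignment.to_csv(path, index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, encoding="utf-8-sig")
    need = {"measurement_id", "subject_id", "partition"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: split manifest needs columns {sorted(need)}")
    df["measurement_id"] = df["measurement_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    return SplitAssignment(assignment=df)
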