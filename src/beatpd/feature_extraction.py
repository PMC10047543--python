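"""Windowing and the two named feature families.

Segments are partitioned into non-overlapping 30-second windows, each
inheriting the labels of its parent observation.  Two feature sets are
computed:

* ``generic`` -- single-channel time-series features on the RMS-combined
  (vector-magnitude) signal: data quantiles, mean, sum, peak count,
  FFT DC coefficient, band powers, spectral entropy, etc.;
* ``actigraphy`` -- exactly 16 per-window triaxial features in the
  actigraphy tradition: vector-magnitude summaries, dominant frequency,
  counts-per-minute, inter-axis correlations, per-axis statistics.

Spectral features are computed on a uniform grid obtained by linear
interpolation of the (possibly gappy) raw samples; time-domain features
use the raw samples unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data_model_io import Segment

logger = logging.getLogger("beatpd")

#: Deterministic column order of the generic feature set.
GENERIC_FEATURES = (
    ["mean", "sum_values", "median", "variance", "standard_deviation",
     "minimum", "maximum"]
    + [f"quantile_q_{q:.1f}" for q in
       (0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9)]
    + ["number_peaks_n_1", "zero_crossings",
       "fft_coefficient_0_real", "fft_coefficient_0_abs",
       "band_power_0.5_3", "band_power_3_7", "band_power_7_12",
       "spectral_entropy", "dominant_frequency", "dominant_power",
       "abs_energy", "mean_abs_change", "root_mean_square", "skewness",
       "kurtosis", "interquartile_range", "signal_range",
       "mean_deviation_from_1g", "longest_strike_above_mean",
       "count_above_mean"]
)

#: The fixed 16-feature actigraphy set (triaxial).
ACTIGRAPHY_FEATURES = (
    "vm_mean", "vm_sd", "vm_max", "dominant_frequency", "dominant_power",
    "spectral_entropy", "band_power_3_7", "cpm", "corr_xy", "corr_xz",
    "corr_yz", "mean_x", "mean_y", "mean_z", "axis_sd_mean", "jerk_rms",
)

#: Covariate columns appended in ``with_covariates`` mode.
COVARIATE_FEATURES = (
    "age", "gender_code", "updrs_part1_total", "updrs_part2_total",
    "updrs_4_1", "updrs_4_2", "updrs_4_3", "updrs_4_4", "updrs_4_5",
    "updrs_4_6", "updrs_3_on_sum", "updrs_3_off_sum", "updrs_3_pc1",
)


@dataclass
class Window:
    """One 30-second slice of a segment, with provenance."""

    measurement_id: str
    window_index: int
    t: np.ndarray
    data: np.ndarray  # (n,) mono or (n, 3) triaxial
    device: str = "watch"
    subject_id: str = ""
    sampling_rate: float = 50.0
    width: float = 30.0


def combine_rms(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes (vector magnitude)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not len(x) == len(y) == len(z):
        raise ValueError("axis length mismatch")
    return np.sqrt(x ** 2 + y ** 2 + z ** 2)


def window_segment(segment: Segment, width: float = 30.0,
                   sampling_rate: float | None = None,
                   min_fraction: float = 0.5) -> list[Window]:
    """Partition a segment into non-overlapping ``[k*w, (k+1)*w)`` windows.

    Windows holding fewer than ``min_fraction`` of the expected sample
    count are dropped (and logged).  The trailing partial window is
    discarded.
    """
    t, xyz = segment.arrays()
    if len(t) == 0:
        return []
    if sampling_rate is None:
        dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
        sampling_rate = 1.0 / dt
    span = t[-1] - t[0]
    n_windows = int(np.floor((span + 1.0 / sampling_rate) / width))
    expected = width * sampling_rate
    out = []
    t0 = t[0]
    for k in range(n_windows):
        lo, hi = t0 + k * width, t0 + (k + 1) * width
        mask = (t >= lo) & (t < hi)
        count = int(mask.sum())
        if count < min_fraction * expected:
            logger.info("dropped window %d of %s (%d/%d samples)",
                        k, segment.measurement_id, count, int(expected))
            continue
        out.append(Window(segment.measurement_id, k, t[mask] - lo,
                          xyz[mask], device=segment.device,
                          subject_id=segment.subject_id,
                          sampling_rate=sampling_rate, width=width))
    return out


# ---------------------------------------------------------------------------
# Spectral helpers
# ---------------------------------------------------------------------------

def _uniform_grid(t: np.ndarray, v: np.ndarray, fs: float,
                  width: float) -> np.ndarray:
    """Linear interpolation onto a uniform grid of ``width * fs`` samples."""
    n = int(round(width * fs))
    grid = (t[0] if len(t) else 0.0) + np.arange(n) / fs
    return np.interp(grid, t, v)


def _psd(v: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram, |rfft|^2 scaled to power spectral density."""
    n = len(v)
    spec = np.fft.rfft(v)
    psd = (spec.real ** 2 + spec.imag ** 2) / (fs * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
                hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _spectral_entropy(psd: np.ndarray) -> float:
    """Normalised Shannon entropy of the DC-excluded power spectrum, in [0, 1]."""
    p = psd[1:]
    total = p.sum()
    # constant signals leave only numerical residue outside the DC bin
    if total <= max(psd.sum(), 1.0) * 1e-10 or len(p) < 2:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def _dominant(freqs: np.ndarray, psd: np.ndarray, lo: float = 0.3,
              hi: float = 15.0) -> tuple[float, float]:
    mask = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not mask.any():
        return 0.0, 0.0
    idx = np.argmax(psd[mask])
    return float(freqs[mask][idx]), float(psd[mask][idx])


def number_peaks(v: np.ndarray, support: int = 1) -> int:
    """Count samples strictly greater than their ``support`` neighbours
    on both sides."""
    n = len(v)
    if n < 2 * support + 1:
        return 0
    peaks = np.ones(n - 2 * support, dtype=bool)
    centre = v[support:n - support]
    for d in range(1, support + 1):
        peaks &= centre > v[support - d:n - support - d]
        peaks &= centre > v[support + d:n - support + d]
    return int(peaks.sum())


# ---------------------------------------------------------------------------
# Feature sets
# ---------------------------------------------------------------------------

def generic_features(window: Window) -> dict[str, float]:
    """Generic single-channel features on the RMS-combined signal."""
    if window.data.ndim == 2:
        v = combine_rms(window.data[:, 0], window.data[:, 1],
                        window.data[:, 2])
    else:
        v = np.asarray(window.data, dtype=float)
    if len(v) < 2:
        raise ValueError("window must contain at least 2 samples")
    fs = window.sampling_rate
    u = _uniform_grid(window.t, v, fs, window.width)
    freqs, psd = _psd(u, fs)
    centred = v - v.mean()
    q_levels = (0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9, 0.25, 0.5, 0.75)
    q_vals = np.quantile(v, q_levels)
    q = {f"quantile_q_{p:.1f}": float(q_vals[i])
         for i, p in enumerate(q_levels[:8])}
    dom_f, dom_p = _dominant(freqs, psd)
    diffs = np.abs(np.diff(v))
    above = v > v.mean()
    # longest run of consecutive samples above the mean
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, above.view(np.int8), 0])))
    longest = int(runs[::2].max()) if runs.size else 0
    sd = float(v.std())
    feats = {
        "mean": float(v.mean()),
        "sum_values": float(v.sum()),
        "median": float(q_vals[9]),
        "variance": float(v.var()),
        "standard_deviation": sd,
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        **q,
        "number_peaks_n_1": float(number_peaks(v, 1)),
        "zero_crossings": float((np.diff(np.signbit(centred)) != 0).sum()),
        "fft_coefficient_0_real": float(np.fft.rfft(u)[0].real),
        "fft_coefficient_0_abs": float(np.abs(np.fft.rfft(u)[0])),
        "band_power_0.5_3": _band_power(freqs, psd, 0.5, 3.0),
        "band_power_3_7": _band_power(freqs, psd, 3.0, 7.0),
        "band_power_7_12": _band_power(freqs, psd, 7.0, 12.0),
        "spectral_entropy": _spectral_entropy(psd),
        "dominant_frequency": dom_f,
        "dominant_power": dom_p,
        "abs_energy": float((v ** 2).sum()),
        "mean_abs_change": float(diffs.mean()) if diffs.size else 0.0,
        "root_mean_square": float(np.sqrt((v ** 2).mean())),
        "skewness": _moment_ratio(centred, 3, sd),
        "kurtosis": _moment_ratio(centred, 4, sd),
        "interquartile_range": float(q_vals[10] - q_vals[8]),
        "signal_range": float(v.max() - v.min()),
        "mean_deviation_from_1g": float(np.abs(v - 1.0).mean()),
        "longest_strike_above_mean": float(longest),
        "count_above_mean": float(above.sum()),
    }
    return {k: feats[k] for k in GENERIC_FEATURES}


def _moment_ratio(centred: np.ndarray, order: int, sd: float) -> float:
    if sd == 0:
        return 0.0
    return float((centred ** order).mean() / sd ** order)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        logger.info("zero-variance axis: correlation reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def actigraphy_features(window: Window) -> dict[str, float]:
    """The fixed 16-feature triaxial actigraphy set.

    ``cpm`` integrates ``|VM - 1 g|`` over the window and scales it to a
    per-minute rate, mimicking conventional Actigraph count reports.
    """
    if window.data.ndim != 2 or window.data.shape[1] != 3:
        raise ValueError("actigraphy features require triaxial data")
    x, y, z = window.data[:, 0], window.data[:, 1], window.data[:, 2]
    vm = combine_rms(x, y, z)
    fs = window.sampling_rate
    u = _uniform_grid(window.t, vm, fs, window.width)
    freqs, psd = _psd(u - u.mean(), fs)
    dom_f, dom_p = _dominant(freqs, psd, 0.3, 15.0)
    jerk = np.diff(u) * fs
    feats = {
        "vm_mean": float(vm.mean()),
        "vm_sd": float(vm.std()),
        "vm_max": float(vm.max()),
        "dominant_frequency": dom_f,
        "dominant_power": dom_p,
        "spectral_entropy": _spectral_entropy(psd),
        "band_power_3_7": _band_power(freqs, psd, 3.0, 7.0),
        "cpm": float(np.abs(vm - 1.0).sum() / fs / (window.width / 60.0)),
        "corr_xy": _safe_corr(x, y),
        "corr_xz": _safe_corr(x, z),
        "corr_yz": _safe_corr(y, z),
        "mean_x": float(x.mean()),
        "mean_y": float(y.mean()),
        "mean_z": float(z.mean()),
        "axis_sd_mean": float(np.mean([x.std(), y.std(), z.std()])),
        "jerk_rms": float(np.sqrt((jerk ** 2).mean())) if jerk.size else 0.0,
    }
    return {k: feats[k] for k in ACTIGRAPHY_FEATURES}


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def extract_features(segments, feature_set: str = "generic",
                     width: float = 30.0,
                     sampling_rate: float | None = None) -> pd.DataFrame:
    """Window every segment and compute one feature set per window.

    Returns a table with ``measurement_id, subject_id, window_index,
    device`` followed by the feature columns in their documented order.
    """
    fn = {"generic": generic_features,
          "actigraphy": actigraphy_features}.get(feature_set)
    if fn is None:
        raise ValueError(f"unknown feature set {feature_set!r}")
    rows = []
    for seg in segments:
        for w in window_segment(seg, width=width, sampling_rate=sampling_rate):
            row = {"measurement_id": w.measurement_id,
                   "subject_id": w.subject_id,
                   "window_index": w.window_index,
                   "device": w.device}
            row.update(fn(w))
            rows.append(row)
    cols = ["measurement_id", "subject_id", "window_index", "device"]
    cols += list(GENERIC_FEATURES if feature_set == "generic"
                 else ACTIGRAPHY_FEATURES)
    df = pd.DataFrame(rows, columns=cols)
    # No-missing-values contract: any residual NaN becomes the column median.
    feat_cols = cols[4:]
    if df[feat_cols].isna().any().any():
        logger.warning("imputing %d missing feature values with column medians",
                       int(df[feat_cols].isna().sum().sum()))
        df[feat_cols] = df[feat_cols].fillna(df[feat_cols].median())
    return df


def part3_pca_scores(covariates: pd.DataFrame) -> pd.Series:
    """First principal-direction score of the MDS-UPDRS Part III items.

    Computed across subjects on the concatenated on- and off-state item
    vectors; all-identical inputs yield zero scores.
    """
    from sklearn.decomposition import PCA

    item_cols = [c for c in covariates.columns
                 if c.startswith("updrs_3_on_") or c.startswith("updrs_3_off_")]
    X = covariates[item_cols].to_numpy(dtype=float)
    if len(X) < 2 or np.allclose(X.var(axis=0), 0):
        return pd.Series(np.zeros(len(X)), index=covariates.index)
    scores = PCA(n_components=1, random_state=0).fit_transform(X)[:, 0]
    # Fix the sign so higher score means higher total motor burden.
    if np.corrcoef(scores, X.sum(axis=1))[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=covariates.index)


def covariate_block(covariates: pd.DataFrame) -> pd.DataFrame:
    """Model-ready per-subject covariate features."""
    on_cols = [c for c in covariates.columns if c.startswith("updrs_3_on_")]
    off_cols = [c for c in covariates.columns if c.startswith("updrs_3_off_")]
    out = pd.DataFrame({
        "subject_id": covariates["subject_id"].astype(str),
        "age": covariates["age"].astype(float),
        "gender_code": (covariates["gender"] == "M").astype(float),
        "updrs_part1_total": covariates["updrs_part1_total"].astype(float),
        "updrs_part2_total": covariates["updrs_part2_total"].astype(float),
        "updrs_3_on_sum": covariates[on_cols].sum(axis=1).astype(float),
        "updrs_3_off_sum": covariates[off_cols].sum(axis=1).astype(float),
    })
    for i in range(1, 7):
        out[f"updrs_4_{i}"] = covariates[f"updrs_4_{i}"].astype(float)
    out["updrs_3_pc1"] = part3_pca_scores(covariates).to_numpy()
    return out[["subject_id", *COVARIATE_FEATURES]]


def assemble_design_matrix(features: pd.DataFrame, labels: pd.DataFrame,
                           covariates: pd.DataFrame | None = None,
                           mode: str = "sensor_only") -> pd.DataFrame:
    """Join window features with inherited labels (and covariates).

    ``labels`` must be harmonized and carry ``measurement_id`` plus the
    symptom columns.  In ``with_covariates`` mode the per-subject
    covariate block (age, gender, UPDRS totals/items/PC1) is appended;
    missing covariates are imputed with the cohort median (logged).
    Multi-device rows are kept separate.
    """
    if mode not in ("sensor_only", "with_covariates"):
        raise ValueError(f"unknown mode {mode!r}")
    label_cols = ["measurement_id"] + [c for c in
                                       ("cohort_id", "on_off", "dyskinesia",
                                        "tremor")
                                       if c in labels.columns]
    df = features.merge(labels[label_cols], on="measurement_id", how="left")
    if mode == "with_covariates":
        if covariates is None:
            raise ValueError("with_covariates mode requires a covariate table")
        block = covariate_block(covariates)
        df = df.merge(block, on="subject_id", how="left")
        cov_cols = list(COVARIATE_FEATURES)
        if df[cov_cols].isna().any().any():
            logger.info("imputing missing covariates with cohort medians")
            df[cov_cols] = df[cov_cols].fillna(df[cov_cols].median())
    return df
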