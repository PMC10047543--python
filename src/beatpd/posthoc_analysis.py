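"""Subject-level lift, covariate associations and clinical validation.

Lift for a subject is the improvement of a model over the Null baseline,
``Lift = MSE_Null - MSE_model`` (positive means the model beats the
per-subject-mean prediction); its sampling variability is assessed with
paired within-subject bootstrap resamples.  Associations of lift with
subject covariates (test-set size, label variance, reporting lag, age,
MDS-UPDRS parts) use Kendall's tau-b; meta-analysis across models
converts tau to Pearson's r via Greiner's relation ``r = sin(pi*tau/2)``
and pools Fisher z-transformed correlations with a fixed-effect model
(weights ``n - 3``).  Clinical validation compares model predictions on
short clinician-rated task segments against expert ratings using
within-subject Pearson correlation with one-sided p-values (H_A: r > 0),
combined across subjects by Fisher's log p-value method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .challenge_scoring import ScoreTable

logger = logging.getLogger("beatpd")


@dataclass
class LiftRecord:
    """Per-subject improvement of one model over the Null baseline."""

    subject_id: str
    model: str
    lift: float  # MSE_Null - MSE_model
    lift_percent: float  # lift / MSE_Null (NaN when MSE_Null == 0)
    bootstrap: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def significant(self) -> bool:
        """Lift whose bootstrap 2.5th percentile exceeds zero."""
        if self.bootstrap.size == 0:
            return False
        return float(np.percentile(self.bootstrap, 2.5)) > 0


@dataclass
class MetaAnalysisRecord:
    """Fixed-effect pooling of z-transformed correlations."""

    r_values: list[float]
    n_values: list[int]
    pooled_z: float
    pooled_r: float
    se: float
    p_value: float


# ---------------------------------------------------------------------------
# Lift
# ---------------------------------------------------------------------------

def compute_lift(null_table: ScoreTable, model_table: ScoreTable,
                 model: str = "model") -> list[LiftRecord]:
    """Per-subject lift of a model over the Null, point estimates only."""
    records = []
    null_df = null_table.per_subject.set_index("subject_id")
    for row in model_table.per_subject.itertuples():
        mse_null = float(null_df.loc[row.subject_id, "mse"])
        lift = mse_null - float(row.mse)
        pct = lift / mse_null if mse_null > 0 else np.nan
        if mse_null == 0:
            logger.info("subject %s has MSE_Null = 0; percent lift missing",
                        row.subject_id)
        records.append(LiftRecord(str(row.subject_id), model, lift, pct))
    return records


def bootstrap_lift(predictions_model, predictions_null, truth: pd.DataFrame,
                   model: str = "model", B: int = 100,
                   seed: int = 0) -> list[LiftRecord]:
    """Lift records with a paired within-subject bootstrap distribution.

    Both prediction sets are resampled over the same index multisets, so
    each bootstrap iteration yields a paired lift value per subject.
    """
    rng = np.random.default_rng(seed)
    records = []
    for subject, grp in truth.groupby(truth["subject_id"].astype(str)):
        y = grp["label"].to_numpy(dtype=float)
        ids = grp["measurement_id"].astype(str).tolist()
        pm = np.array([float(predictions_model[m]) for m in ids])
        pn = np.array([float(predictions_null[m]) for m in ids])
        e_m = (pm - y) ** 2
        e_n = (pn - y) ** 2
        lift = float(e_n.mean() - e_m.mean())
        mse_null = float(e_n.mean())
        idx = rng.integers(0, len(y), size=(B, len(y)))
        boot = e_n[idx].mean(axis=1) - e_m[idx].mean(axis=1)
        pct = lift / mse_null if mse_null > 0 else np.nan
        records.append(LiftRecord(subject, model, lift, pct, bootstrap=boot))
    return records


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall's tau-b with its two-sided p-value.

    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("constant vector: Kendall tau undefined")
        return np.nan, np.nan
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def tau_to_r(tau: float) -> float:
    """Greiner's relation between Kendall's tau and Pearson's r."""
    if np.isnan(tau):
        return np.nan
    if abs(tau) > 1:
        raise ValueError(f"tau={tau} outside [-1, 1]")
    return float(np.sin(np.pi * tau / 2))


def fixed_effect_meta(r_values, n_values) -> MetaAnalysisRecord:
    """Fixed-effect meta-analysis of correlations on the Fisher z scale.

    ``z_i = atanh(r_i)`` with weights ``w_i = n_i - 3``; the pooled z has
    standard error ``1/sqrt(sum w)`` and a two-sided normal p-value.
    """
    r = np.asarray(r_values, dtype=float)
    n = np.asarray(n_values, dtype=float)
    if len(r) != len(n) or len(r) == 0:
        raise ValueError("paired r and n values required")
    if np.any(n < 4):
        raise ValueError("all sample sizes must be >= 4 (weights n - 3)")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 gives infinite z; shrink r by a small "
                         "epsilon before pooling")
    z = np.arctanh(r)
    w = n - 3
    pooled_z = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(pooled_z / se)))
    return MetaAnalysisRecord(list(map(float, r)), list(map(int, n)),
                              pooled_z, float(np.tanh(pooled_z)), se, p)


def fisher_combined(p_values) -> tuple[float, int, float]:
    """Fisher's method: ``X^2 = -2 sum(log p_i)`` on ``2m`` df."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2 * np.sum(np.log(p)))
    df = 2 * len(p)
    return x2, df, float(stats.chi2.sf(x2, df))


# ---------------------------------------------------------------------------
# Clinical validation
# ---------------------------------------------------------------------------

def clinical_validation(predictions: pd.DataFrame,
                        ratings: pd.DataFrame,
                        min_segments: int = 3) -> dict:
    """Validate predictions against clinician ratings of short task segments.

    ``predictions`` and ``ratings`` both carry ``segment_id, subject_id``
    plus a ``value`` column.  Per subject: Pearson r and one-sided p
    (H_A: r > 0); subjects with fewer than ``min_segments`` rated
    segments or zero-variance ratings are excluded (logged).  Returns
    per-subject results and the Fisher-combined p across subjects.
    """
    merged = predictions.merge(ratings, on=["segment_id", "subject_id"],
                               suffixes=("_pred", "_rating"))
    per_subject = []
    for subject, grp in merged.groupby(merged["subject_id"].astype(str)):
        if len(grp) < min_segments:
            logger.info("clinical validation: subject %s has %d < %d rated "
                        "segments; excluded", subject, len(grp), min_segments)
            continue
        pred = grp["value_pred"].to_numpy(dtype=float)
        rating = grp["value_rating"].to_numpy(dtype=float)
        if rating.std() == 0 or pred.std() == 0:
            logger.info("clinical validation: zero-variance data for subject "
                        "%s; excluded", subject)
            continue
        res = stats.pearsonr(pred, rating, alternative="greater")
        per_subject.append({"subject_id": subject, "n": len(grp),
                            "r": float(res.statistic),
                            "p_one_sided": float(res.pvalue)})
    if not per_subject:
        return {"per_subject": [], "fisher_x2": np.nan, "df": 0,
                "combined_p": np.nan}
    pvals = [min(max(d["p_one_sided"], np.finfo(float).tiny), 1.0)
             for d in per_subject]
    x2, df, combined = fisher_combined(pvals)
    return {"per_subject": per_subject, "fisher_x2": x2, "df": df,
            "combined_p": combined}


# ---------------------------------------------------------------------------
# Covariate association suite
# ---------------------------------------------------------------------------

def covariate_association_suite(lift_records: list[LiftRecord],
                                covariates: pd.DataFrame) -> pd.DataFrame:
    """Associate per-subject lift with subject covariates, per model and
    pooled across models.

    ``covariates``: one row per subject (``subject_id`` plus numeric
    covariate columns, e.g. n, label variance, reporting lag, age, UPDRS
    parts).  Constant covariates are skipped.  Pooling converts each
    model's tau to r and applies the fixed-effect meta-analysis; with a
    single model the pooled value equals that model's converted r.
    """
    lifts = pd.DataFrame([{"subject_id": r.subject_id, "model": r.model,
                           "lift": r.lift} for r in lift_records])
    if lifts.empty:
        return pd.DataFrame(columns=["covariate", "model", "tau", "p",
                                     "r", "n"])
    cov = covariates.set_index(covariates["subject_id"].astype(str))
    cov_cols = [c for c in covariates.columns
                if c != "subject_id"
                and pd.api.types.is_numeric_dtype(covariates[c])]
    rows = []
    for cov_name in cov_cols:
        values = cov[cov_name]
        if values.nunique() <= 1:
            continue
        per_model = []
        for model, grp in lifts.groupby("model"):
            x = grp.set_index("subject_id")["lift"]
            shared = [s for s in x.index if s in values.index]
            if len(shared) < 3:
                continue
            tau, p = kendall_tau(x.loc[shared].to_numpy(),
                                 values.loc[shared].to_numpy())
            if np.isnan(tau):
                continue
            r = tau_to_r(tau)
            rows.append({"covariate": cov_name, "model": model, "tau": tau,
                         "p": p, "r": r, "n": len(shared)})
            per_model.append((r, len(shared)))
        per_model = [(r, n) for r, n in per_model if n >= 4]
        if per_model:
            r_vals = [min(max(r, -0.999), 0.999) for r, _ in per_model]
            n_vals = [n for _, n in per_model]
            meta = fixed_effect_meta(r_vals, n_vals)
            rows.append({"covariate": cov_name, "model": "__pooled__",
                         "tau": np.nan, "p": meta.p_value,
                         "r": meta.pooled_r,
                         "n": int(np.sum(n_vals))})
    return pd.DataFrame(rows, columns=["covariate", "model", "tau", "p",
                                       "r", "n"])


def subject_covariate_table(labels: pd.DataFrame,
                            covariates: pd.DataFrame,
                            split_test_counts: pd.Series,
                            symptom: str) -> pd.DataFrame:
    """Assemble the per-subject covariates the association suite uses:
    n (test observations), label variance, mean reporting lag, age and
    UPDRS part totals."""
    per_subject = []
    for subject, grp in labels.groupby(labels["subject_id"].astype(str)):
        values = grp[symptom].dropna()
        lag = grp["reporting_lag"] if "reporting_lag" in grp else pd.Series(
            dtype=float)
        per_subject.append({
            "subject_id": subject,
            "n_test": float(split_test_counts.get(subject, np.nan)),
            "label_variance": float(values.var(ddof=1))
            if len(values) > 1 else np.nan,
            "reporting_lag": float(lag.mean()) if len(lag) else np.nan,
        })
    out = pd.DataFrame(per_subject)
    keep = ["subject_id", "age", "updrs_part1_total", "updrs_part2_total"]
    on_cols = [c for c in covariates.columns if c.startswith("updrs_3_on_")]
    off_cols = [c for c in covariates.columns if c.startswith("updrs_3_off_")]
    p4_cols = [c for c in covariates.columns if c.startswith("updrs_4_")]
    cov = covariates.copy()
    cov["subject_id"] = cov["subject_id"].astype(str)
    if on_cols:
        cov["updrs_part3_on_total"] = cov[on_cols].sum(axis=1)
        keep.append("updrs_part3_on_total")
    if off_cols:
        cov["updrs_part3_off_total"] = cov[off_cols].sum(axis=1)
        keep.append("updrs_part3_off_total")
    if p4_cols:
        cov["updrs_part4_total"] = cov[p4_cols].sum(axis=1)
        keep.append("updrs_part4_total")
    keep = [c for c in keep if c in cov.columns]
    return out.merge(cov[keep], on="subject_id", how="left")
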