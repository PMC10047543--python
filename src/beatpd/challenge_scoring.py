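"""Submission scoring: weighted MSE, paired bootstraps, significance.

Predictions are scored per subject (MSE_k over that subject's test
observations) and aggregated with sqrt(n_k) weights:

    WMSE = sum_k sqrt(n_k) * MSE_k / sum_k sqrt(n_k)

which downweights subjects contributing many observations.  Submissions
are compared to the Null model (per-subject training-label mean) with a
paired bootstrap: each iteration resamples every subject's test
observations with replacement, keeping n_k fixed, and applies the same
resampled index multiset to every model, so per-iteration scores are
directly comparable.  The p-value versus Null is the fraction of
iterations in which the Null model scores strictly lower, with ties
counted as one half (a submission identical to the Null thereby gets
p = 0.5 rather than the pathological 0 a strict rule would give).
Distinguishability of two submissions uses the one-sided Wilcoxon
signed-rank test on the paired bootstrap scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("beatpd")


class ScoringError(ValueError):
    """Raised for incomplete predictions or degenerate score requests."""


@dataclass
class ScoreTable:
    """Per-subject MSEs, test counts and the weighted aggregate."""

    per_subject: pd.DataFrame  # subject_id, n, mse

    @property
    def wmse(self) -> float:
        return weighted_mse(self)

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)

    def mse_of(self, subject_id: str) -> float:
        row = self.per_subject.loc[
            self.per_subject["subject_id"] == subject_id, "mse"]
        if row.empty:
            raise ScoringError(f"subject {subject_id!r} not in score table")
        return float(row.iloc[0])


@dataclass
class BootstrapResult:
    """Paired bootstrap WMSE distributions for several models."""

    scores: pd.DataFrame  # B rows, one column per model
    point_wmse: dict[str, float]
    B: int
    seed: int


def _align(predictions: Mapping[str, float] | pd.Series,
           truth: pd.DataFrame) -> np.ndarray:
    """Order predictions by the truth table; missing values are an error."""
    if isinstance(predictions, pd.Series):
        predictions = predictions.to_dict()
    missing = [m for m in truth["measurement_id"] if m not in predictions]
    if missing:
        raise ScoringError(
            f"missing predictions for {len(missing)} measurements "
            f"(e.g. {missing[:3]}); missing values are not allowed")
    out = np.array([float(predictions[m]) for m in truth["measurement_id"]])
    if not np.isfinite(out).all():
        raise ScoringError("non-finite prediction values")
    return out


def subject_mse(predictions: Mapping[str, float] | pd.Series,
                truth: pd.DataFrame, subject_id: str) -> float:
    """Mean squared error over one subject's test observations."""
    sub = truth[truth["subject_id"].astype(str) == str(subject_id)]
    if sub.empty:
        raise ScoringError(f"no test observations for subject {subject_id!r}")
    pred = _align(predictions, sub)
    return float(np.mean((pred - sub["label"].to_numpy(dtype=float)) ** 2))


def score_predictions(predictions: Mapping[str, float] | pd.Series,
                      truth: pd.DataFrame) -> ScoreTable:
    """Build the per-subject score table for one prediction set.

    ``truth`` columns: measurement_id, subject_id, label.
    """
    rows = []
    for subject, grp in truth.groupby(truth["subject_id"].astype(str)):
        pred = _align(predictions, grp)
        mse = float(np.mean((pred - grp["label"].to_numpy(dtype=float)) ** 2))
        rows.append((subject, len(grp), mse))
    if not rows:
        raise ScoringError("empty truth table")
    table = pd.DataFrame(rows, columns=["subject_id", "n", "mse"])
    return ScoreTable(per_subject=table.sort_values("subject_id")
                      .reset_index(drop=True))


def weighted_mse(table: ScoreTable | pd.DataFrame) -> float:
    """sqrt(n_k)-weighted mean of the per-subject MSEs."""
    df = table.per_subject if isinstance(table, ScoreTable) else table
    if df.empty:
        raise ScoringError("empty score table")
    w = np.sqrt(df["n"].to_numpy(dtype=float))
    return float(np.sum(w * df["mse"].to_numpy(dtype=float)) / np.sum(w))


def bootstrap_scores(prediction_sets: Mapping[str, Mapping[str, float] | pd.Series],
                     truth: pd.DataFrame, B: int = 1000,
                     seed: int = 0) -> BootstrapResult:
    """Paired bootstrap of WMSE for several complete prediction sets.

    Each iteration resamples every subject's observations with
    replacement (n_k preserved); the same index multiset is applied to
    every model, making per-iteration scores paired.
    """
    if B < 1:
        raise ScoringError("B must be >= 1")
    names = list(prediction_sets)
    errors: dict[str, list[np.ndarray]] = {m: [] for m in names}
    subject_groups = []
    for subject, grp in truth.groupby(truth["subject_id"].astype(str)):
        y = grp["label"].to_numpy(dtype=float)
        subject_groups.append((subject, len(grp)))
        for m in names:
            pred = _align(prediction_sets[m], grp)
            errors[m].append((pred - y) ** 2)
    rng = np.random.default_rng(seed)
    weights = np.sqrt([n for _, n in subject_groups])
    wsum = weights.sum()
    boot = {m: np.zeros(B) for m in names}
    for k, (_, n_k) in enumerate(subject_groups):
        idx = rng.integers(0, n_k, size=(B, n_k))
        for m in names:
            mse_k = errors[m][k][idx].mean(axis=1)
            boot[m] += weights[k] * mse_k
    scores = pd.DataFrame({m: boot[m] / wsum for m in names})
    point = {m: weighted_mse(score_predictions(prediction_sets[m], truth))
             for m in names}
    return BootstrapResult(scores=scores, point_wmse=point, B=B, seed=seed)


def pvalue_vs_null(result: BootstrapResult, model: str,
                   null_name: str = "Null", ties: str = "half") -> float:
    """Fraction of bootstrap iterations in which the Null model wins.

    ``ties="half"`` counts exactly tied iterations as one half;
    ``ties="strict"`` ignores them (the literal wording of the rule).
    """
    for name in (model, null_name):
        if name not in result.scores.columns:
            raise ScoringError(f"model {name!r} absent from bootstrap result")
    null = result.scores[null_name].to_numpy()
    sub = result.scores[model].to_numpy()
    wins = (null < sub).sum()
    if ties == "half":
        wins = wins + 0.5 * (null == sub).sum()
    elif ties != "strict":
        raise ValueError("ties must be 'half' or 'strict'")
    return float(wins / result.B)


def distinguishability(result: BootstrapResult, model_a: str,
                       model_b: str) -> float:
    """One-sided Wilcoxon signed-rank p for A's bootstrap WMSEs < B's.

    Zero differences are dropped; if every difference is zero the models
    are indistinguishable and p = 1 by convention.
    """
    a = result.scores[model_a].to_numpy()
    b = result.scores[model_b].to_numpy()
    diff = a - b
    if np.all(diff == 0):
        logger.info("distinguishability: all bootstrap differences zero")
        return 1.0
    res = stats.wilcoxon(a, b, alternative="less", zero_method="wilcox")
    return float(res.pvalue)


def leaderboard(prediction_sets: Mapping[str, Mapping[str, float] | pd.Series],
                truth: pd.DataFrame, B: int = 1000, seed: int = 0,
                null_name: str = "Null",
                alpha: float = 0.05) -> pd.DataFrame:
    """Rank submissions by WMSE with significance versus the Null model.

    Ties in WMSE break lexicographically by submission id.  Flags both
    the strictly-better-than-Null and the significantly-better sets.
    """
    result = bootstrap_scores(prediction_sets, truth, B=B, seed=seed)
    rows = []
    has_null = null_name in prediction_sets
    for name in sorted(prediction_sets):
        wmse = result.point_wmse[name]
        if has_null and name != null_name:
            p = pvalue_vs_null(result, name, null_name)
            better = wmse < result.point_wmse[null_name]
            significant = p < alpha
        else:
            p, better, significant = np.nan, False, False
        rows.append((name, wmse, p, better, significant))
    df = pd.DataFrame(rows, columns=["submission_id", "wmse", "p_vs_null",
                                     "strictly_better_than_null",
                                     "significant_vs_null"])
    df = df.sort_values(["wmse", "submission_id"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def write_score_report(table: ScoreTable, submission_id: str,
                       path: str | Path, p_vs_null: float | None = None,
                       B: int | None = None, seed: int | None = None) -> None:
    """Persist a score report as JSON."""
    report = {
        "submission_id": submission_id,
        "wmse": weighted_mse(table),
        "per_subject": [
            {"subject": str(r.subject_id), "n": int(r.n), "mse": float(r.mse)}
            for r in table.per_subject.itertuples()
        ],
        "p_vs_null": p_vs_null,
        "B": B,
        "seed": seed,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
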