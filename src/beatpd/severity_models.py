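"""Severity models: the Null baseline and the two winning archetypes.

* ``NullModel`` predicts each subject's training-label mean -- the best
  possible prediction in the absence of any sensor information.
* ``PerSubjectModel`` fits one random-forest regressor per
  subject-symptom combination on window-level features, tunes
  hyperparameters by random search over grouped 5-fold cross-validation
  (windows of one observation never straddle folds), and predicts an
  observation as the median of its window predictions.
* ``GlobalModel`` fits one random forest per cohort on window-level
  features plus subject covariates and predicts an observation as the
  mean of its window predictions.

Observation-level predictions are clipped to the symptom's harmonized
label range (clipping can only reduce squared error).  Multi-device
observations are predicted per device and the device-level predictions
averaged.  An observation left with no surviving windows falls back to
the subject's Null prediction, since the scoring rules forbid missing
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, RandomizedSearchCV

from .data_model_io import LABEL_RANGES
from .feature_extraction import COVARIATE_FEATURES

logger = logging.getLogger("beatpd")

_META_COLS = ("measurement_id", "subject_id", "window_index", "device",
              "cohort_id", "on_off", "dyskinesia", "tremor", "label")


@dataclass
class ModelSpec:
    """Archetype, hyperparameter search space and aggregation rule."""

    archetype: str = "per_subject"  # null | per_subject | global
    symptom: str = "tremor"
    n_estimators: tuple[int, int] = (100, 500)
    max_depth_choices: tuple = (3, 5, 10, None)
    min_samples_leaf: tuple[int, int] = (1, 20)
    cv_folds: int = 5
    search_iterations: int = 25
    aggregation: str | None = None  # defaults: median (per_subject), mean (global)
    seed: int = 0

    def resolved_aggregation(self) -> str:
        if self.aggregation is not None:
            return self.aggregation
        return "median" if self.archetype == "per_subject" else "mean"

    def param_distributions(self, rng: np.random.Generator) -> list[dict]:
        """Materialise ``search_iterations`` draws from the search space."""
        draws = []
        for _ in range(self.search_iterations):
            draws.append({
                "n_estimators": int(rng.integers(self.n_estimators[0],
                                                 self.n_estimators[1] + 1)),
                "max_depth": rng.choice(
                    [d if d is None else int(d)
                     for d in self.max_depth_choices]),
                "min_samples_leaf": int(rng.integers(
                    self.min_samples_leaf[0], self.min_samples_leaf[1] + 1)),
            })
        return draws


def feature_columns(design: pd.DataFrame) -> list[str]:
    """Columns of a design matrix that are model inputs."""
    return [c for c in design.columns if c not in _META_COLS]


def label_range(cohort_id: str, symptom: str) -> tuple[float, float]:
    return LABEL_RANGES[(cohort_id, symptom)]


def _clip_to_range(pred: pd.Series, truth_meta: pd.DataFrame,
                   symptom: str) -> pd.Series:
    """Clip observation predictions to each cohort's harmonized range."""
    cohorts = truth_meta.set_index("measurement_id")["cohort_id"]
    lo = pred.index.map(lambda m: label_range(cohorts.get(m, "CIS"), symptom)[0])
    hi = pred.index.map(lambda m: label_range(cohorts.get(m, "CIS"), symptom)[1])
    return pd.Series(np.clip(pred.to_numpy(), lo, hi), index=pred.index)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

class NullModel:
    """Per-subject mean of the training labels."""

    def __init__(self, symptom: str = "tremor") -> None:
        self.symptom = symptom
        self.means_: dict[str, float] = {}

    def fit(self, labels: pd.DataFrame) -> "NullModel":
        """``labels``: one row per training observation with
        ``subject_id`` and ``label``."""
        clean = labels.dropna(subset=["label"])
        if clean.empty:
            raise ValueError("no training labels")
        self.means_ = {
            str(s): float(g["label"].mean())
            for s, g in clean.groupby(clean["subject_id"].astype(str))
        }
        return self

    def predict_subject(self, subject_id: str) -> float:
        key = str(subject_id)
        if key not in self.means_:
            raise KeyError(f"subject {subject_id!r} unseen at training time")
        return self.means_[key]

    def predict(self, observations: pd.DataFrame) -> pd.Series:
        """Predictions indexed by measurement_id."""
        values = [self.predict_subject(s) for s in observations["subject_id"]]
        return pd.Series(values,
                         index=observations["measurement_id"].astype(str))

    def feature_importance(self) -> pd.Series:
        return pd.Series(dtype=float)


# ---------------------------------------------------------------------------
# Shared tree-ensemble machinery
# ---------------------------------------------------------------------------

def _fit_forest(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                spec: ModelSpec, seed: int) -> RandomForestRegressor:
    """Random-search a forest with grouped CV, then refit on all rows."""
    rng = np.random.default_rng(seed)
    candidates = spec.param_distributions(rng)
    n_groups = len(np.unique(groups))
    folds = min(spec.cv_folds, n_groups)
    best_params, best_score = candidates[0], -np.inf
    if folds >= 2 and len(candidates) > 1:
        cv = GroupKFold(n_splits=folds)
        for params in candidates:
            scores = []
            for tr, te in cv.split(X, y, groups):
                model = RandomForestRegressor(random_state=seed, **params)
                model.fit(X[tr], y[tr])
                scores.append(-np.mean((model.predict(X[te]) - y[te]) ** 2))
            score = float(np.mean(scores))
            if score > best_score:
                best_params, best_score = params, score
    final = RandomForestRegressor(random_state=seed, **best_params)
    final.fit(X, y)
    return final


def _aggregate(window_preds: pd.DataFrame, how: str) -> pd.Series:
    """Windows -> device-level -> observation-level predictions."""
    agg = np.median if how == "median" else np.mean
    per_device = window_preds.groupby(["measurement_id", "device"])["pred"] \
        .apply(lambda v: float(agg(v.to_numpy())))
    return per_device.groupby(level="measurement_id").mean()


class _ForestModelBase:
    """Common predict/importance plumbing for the two archetypes."""

    spec: ModelSpec
    symptom: str

    def _window_predictions(self, design: pd.DataFrame) -> pd.DataFrame:
        raise NotImplementedError

    def predict(self, design: pd.DataFrame,
                null_model: NullModel | None = None) -> pd.Series:
        """Observation-level predictions indexed by measurement_id.

        ``design`` is a window-level design matrix for the test
        observations.  Observations absent from ``design`` (all windows
        dropped) fall back to the Null prediction when a Null model is
        supplied.
        """
        preds = self._window_predictions(design)
        how = self.spec.resolved_aggregation()
        obs = _aggregate(preds, how)
        meta = design[["measurement_id", "cohort_id"]].drop_duplicates() \
            if "cohort_id" in design.columns else \
            pd.DataFrame({"measurement_id": obs.index, "cohort_id": "CIS"})
        obs = _clip_to_range(obs, meta, self.symptom)
        if null_model is not None:
            missing = set(design["measurement_id"].astype(str)) - set(obs.index)
            for mid in sorted(missing):
                subj = design.loc[design["measurement_id"] == mid,
                                  "subject_id"].iloc[0]
                logger.info("no surviving windows for %s; Null fallback", mid)
                obs.loc[mid] = null_model.predict_subject(subj)
        return obs

    def feature_importance(self) -> pd.Series:
        raise NotImplementedError


class PerSubjectModel(_ForestModelBase):
    """One tuned random forest per subject-symptom combination."""

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.symptom = spec.symptom
        self.models_: dict[str, RandomForestRegressor | float] = {}
        self.columns_: list[str] = []

    def fit(self, design: pd.DataFrame) -> "PerSubjectModel":
        """``design``: window rows with ``label`` (the inherited
        observation label), ``measurement_id``, ``subject_id`` and
        feature columns."""
        self.columns_ = feature_columns(design)
        for i, (subject, grp) in enumerate(
                design.groupby(design["subject_id"].astype(str))):
            y = grp["label"].to_numpy(dtype=float)
            if len(np.unique(y)) < 2:
                logger.info("subject %s has a single label value; "
                            "constant model", subject)
                self.models_[subject] = float(y[0])
                continue
            X = grp[self.columns_].to_numpy(dtype=float)
            groups = grp["measurement_id"].to_numpy()
            self.models_[subject] = _fit_forest(
                X, y, groups, self.spec, seed=self.spec.seed + i)
        return self

    def _window_predictions(self, design: pd.DataFrame) -> pd.DataFrame:
        frames = []
        for subject, grp in design.groupby(design["subject_id"].astype(str)):
            model = self.models_.get(subject)
            if model is None:
                raise KeyError(f"subject {subject!r} unseen at training time")
            if isinstance(model, float):
                pred = np.full(len(grp), model)
            else:
                pred = model.predict(grp[self.columns_].to_numpy(dtype=float))
            frames.append(pd.DataFrame({
                "measurement_id": grp["measurement_id"].astype(str),
                "device": grp["device"] if "device" in grp else "watch",
                "pred": pred}))
        return pd.concat(frames, ignore_index=True)

    def feature_importance(self) -> pd.Series:
        """Mean impurity importance across subject models, normalised."""
        forests = [m for m in self.models_.values()
                   if isinstance(m, RandomForestRegressor)]
        if not forests:
            return pd.Series(dtype=float)
        imp = np.mean([f.feature_importances_ for f in forests], axis=0)
        return normalize_importances(pd.Series(imp, index=self.columns_))


class GlobalModel(_ForestModelBase):
    """One random forest per cohort, covariates included."""

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.symptom = spec.symptom
        self.model_: RandomForestRegressor | None = None
        self.columns_: list[str] = []

    def fit(self, design: pd.DataFrame) -> "GlobalModel":
        subjects = design["subject_id"].astype(str).nunique()
        if subjects < 2:
            raise ValueError("a global model needs at least 2 subjects")
        self.columns_ = feature_columns(design)
        X = design[self.columns_].to_numpy(dtype=float)
        y = design["label"].to_numpy(dtype=float)
        groups = design["measurement_id"].to_numpy()
        self.model_ = _fit_forest(X, y, groups, self.spec,
                                  seed=self.spec.seed)
        return self

    def _window_predictions(self, design: pd.DataFrame) -> pd.DataFrame:
        assert self.model_ is not None, "fit first"
        pred = self.model_.predict(design[self.columns_].to_numpy(dtype=float))
        return pd.DataFrame({
            "measurement_id": design["measurement_id"].astype(str),
            "device": design["device"] if "device" in design else "watch",
            "pred": pred})

    def feature_importance(self) -> pd.Series:
        assert self.model_ is not None, "fit first"
        return normalize_importances(
            pd.Series(self.model_.feature_importances_, index=self.columns_))

    def covariate_importance_share(self) -> float:
        """Fraction of importance mass on the covariate columns."""
        imp = self.feature_importance()
        cov = [c for c in imp.index if c in COVARIATE_FEATURES]
        return float(imp[cov].sum())


def normalize_importances(imp: pd.Series) -> pd.Series:
    total = imp.sum()
    if total <= 0:
        return imp
    return (imp / total).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def fit_null(train_labels: pd.DataFrame, symptom: str) -> NullModel:
    """``train_labels``: measurement_id, subject_id and the symptom column."""
    df = pd.DataFrame({"subject_id": train_labels["subject_id"],
                       "label": train_labels[symptom]})
    return NullModel(symptom).fit(df)


def fit_per_subject(design: pd.DataFrame, symptom: str,
                    spec: ModelSpec | None = None) -> PerSubjectModel:
    spec = spec or ModelSpec(archetype="per_subject", symptom=symptom)
    spec.archetype, spec.symptom = "per_subject", symptom
    df = design.rename(columns={symptom: "label"})
    return PerSubjectModel(spec).fit(df.dropna(subset=["label"]))


def fit_global(design: pd.DataFrame, symptom: str,
               spec: ModelSpec | None = None) -> dict[str, GlobalModel]:
    """One fitted model per cohort present in the design matrix."""
    spec = spec or ModelSpec(archetype="global", symptom=symptom)
    spec.archetype, spec.symptom = "global", symptom
    df = design.rename(columns={symptom: "label"}).dropna(subset=["label"])
    out = {}
    for cohort, grp in df.groupby("cohort_id"):
        cohort_spec = ModelSpec(**{**vars(spec)})
        out[str(cohort)] = GlobalModel(cohort_spec).fit(grp)
    return out


def predict_observation(model, design: pd.DataFrame,
                        null_model: NullModel | None = None) -> pd.Series:
    """Observation predictions for a fitted archetype (or cohort dict)."""
    if isinstance(model, dict):
        parts = [m.predict(design[design["cohort_id"] == c], null_model)
                 for c, m in model.items()
                 if (design["cohort_id"] == c).any()]
        return pd.concat(parts).sort_index()
    return model.predict(design, null_model)
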