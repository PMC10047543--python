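"""Heterogeneous ensembles over base prediction sets.

The construction follows a nested cross-validation protocol: the
training observations are split into six within-subject stratified
folds; five of them form a traditional CV loop that generates
out-of-fold base predictions and tunes ensemble parameters, and the
sixth ("evaluation") fold is used only to pick one unsupervised and one
supervised ensemble before the final refit on the full training data.

Families implemented:

* unsupervised aggregation -- row-wise mean or median of the bases;
* stacking -- a meta-regressor over the base predictions, on raw,
  z-scored or per-subject variants, with five meta-learner families
  (unregularized linear, L1 linear, L2 linear, random forest,
  gradient-boosted trees);
* CES -- Caruana-style greedy forward selection with replacement into an
  averaged ensemble, stopping when no addition improves the weighted MSE;
* subset + L2-linear search -- exhaustive enumeration of base subsets
  (bounded at 12 bases), each fitted as a ridge combination on an 80%
  learn split and scored on the held-out 20%.  This systematic search
  stands in for reinforcement-learning ensemble selection, whose
  published optimum on five bases collapsed to an L2-regularized linear
  model over the full base set -- the exact model this family contains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from .challenge_scoring import score_predictions, weighted_mse

logger = logging.getLogger("beatpd")

STACKING_FAMILIES = ("linear", "lasso", "ridge", "random_forest",
                     "gradient_boosting")
STACKING_VARIANTS = ("raw", "z_scored", "per_subject")
DEFAULT_ALPHA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class BasePredictionMatrix:
    """Out-of-fold predictions of several base models on shared rows."""

    frame: pd.DataFrame  # measurement_id, subject_id, truth, fold, bases...
    base_names: list[str]

    def __post_init__(self) -> None:
        need = {"measurement_id", "subject_id", "truth"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"matrix needs columns {sorted(need)}")
        X = self.frame[self.base_names].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite base predictions")

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measurement_id": self.frame["measurement_id"].astype(str),
            "subject_id": self.frame["subject_id"].astype(str),
            "label": self.frame["truth"].astype(float)})

    def X(self) -> np.ndarray:
        return self.frame[self.base_names].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "BasePredictionMatrix":
        return BasePredictionMatrix(self.frame[mask].reset_index(drop=True),
                                    list(self.base_names))

    def wmse_of(self, values: np.ndarray) -> float:
        pred = pd.Series(values,
                         index=self.frame["measurement_id"].astype(str))
        return weighted_mse(score_predictions(pred, self.truth))


def matrix_from_frame(frame: pd.DataFrame) -> BasePredictionMatrix:
    meta = {"measurement_id", "subject_id", "truth", "fold"}
    bases = [c for c in frame.columns if c not in meta]
    return BasePredictionMatrix(frame, bases)


# ---------------------------------------------------------------------------
# Fold plan
# ---------------------------------------------------------------------------

def nested_cv(observations: pd.DataFrame, k: int = 6,
              seed: int = 0) -> pd.Series:
    """Assign each observation to one of ``k`` within-subject folds.

    Folds are stratified within subject on the label: observations are
    grouped by label value, shuffled within group, and dealt round-robin.
    The last fold (``k - 1``) is the evaluation fold.  Subjects with
    fewer than ``k`` observations still get a valid (partial) assignment.
    """
    if k < 2:
        raise ValueError("k must be >= 2; reduce k only down to 2")
    if len(observations) < k:
        raise ValueError(
            f"only {len(observations)} observations for {k} folds; "
            "reduce k")
    rng = np.random.default_rng(seed)
    fold = pd.Series(index=observations["measurement_id"].astype(str),
                     dtype=int, name="fold")
    label_col = "label" if "label" in observations.columns else None
    for subject, grp in observations.groupby(
            observations["subject_id"].astype(str)):
        ids: list[str] = []
        if label_col:
            for _, sub in grp.groupby(grp[label_col], dropna=False):
                mids = sub["measurement_id"].astype(str).tolist()
                rng.shuffle(mids)
                ids.extend(mids)
        else:
            ids = grp["measurement_id"].astype(str).tolist()
            rng.shuffle(ids)
        start = int(rng.integers(0, k))
        for i, mid in enumerate(ids):
            fold.loc[mid] = (start + i) % k
    return fold.astype(int)


# ---------------------------------------------------------------------------
# Unsupervised aggregation
# ---------------------------------------------------------------------------

def aggregate_unsupervised(matrix: BasePredictionMatrix,
                           how: str = "median") -> pd.Series:
    """Row-wise mean or median of the base predictions."""
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    X = matrix.X()
    values = np.mean(X, axis=1) if how == "mean" else np.median(X, axis=1)
    return pd.Series(values, index=matrix.frame["measurement_id"].astype(str))


class UnsupervisedEnsemble:
    """Stateless mean/median aggregator with the common interface."""

    def __init__(self, how: str) -> None:
        self.how = how

    def fit(self, matrix: BasePredictionMatrix) -> "UnsupervisedEnsemble":
        return self

    def predict(self, matrix: BasePredictionMatrix) -> pd.Series:
        return aggregate_unsupervised(matrix, self.how)

    def describe(self) -> dict:
        return {"family": self.how}


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def _singular(X: np.ndarray) -> bool:
    aug = np.column_stack([X, np.ones(len(X))])
    return np.linalg.matrix_rank(aug) < aug.shape[1]


#: Regularization grids searched by inner CV, one per meta-learner family:
#: L1/L2 strength for the linear families, minimum leaf size for the tree
#: families (meta-learners see only a handful of base-prediction columns,
#: so leaf size is their effective regularizer).
META_PARAM_GRIDS = {
    "linear": (0.0,),
    "lasso": DEFAULT_ALPHA_GRID,
    "ridge": DEFAULT_ALPHA_GRID,
    "random_forest": (5, 20, 80),
    "gradient_boosting": (5, 20, 80),
}


def _make_meta(family: str, param: float, seed: int):
    if family == "linear":
        return LinearRegression()
    if family == "lasso":
        return Lasso(alpha=param, max_iter=10000)
    if family == "ridge":
        return Ridge(alpha=param)
    if family == "random_forest":
        return RandomForestRegressor(n_estimators=200,
                                     min_samples_leaf=int(param),
                                     random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingRegressor(min_samples_leaf=int(param),
                                         random_state=seed)
    raise ValueError(f"unknown meta-learner family {family!r}")


class StackingEnsemble:
    """Meta-regressor over base predictions (raw/z-scored/per-subject).

    Regularization strength for the linear families is selected by CV
    over the matrix's fold assignment (inner folds only).
    """

    def __init__(self, family: str = "ridge", variant: str = "raw",
                 param_grid=None, min_subject_obs: int = 10,
                 seed: int = 0) -> None:
        if family not in STACKING_FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if variant not in STACKING_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.family = family
        self.variant = variant
        self.param_grid = tuple(param_grid if param_grid is not None
                                else META_PARAM_GRIDS[family])
        self.min_subject_obs = min_subject_obs
        self.seed = seed
        self.param_: float = self.param_grid[0]
        self.model_ = None
        self.subject_models_: dict[str, object] = {}
        self.norm_: tuple[np.ndarray, np.ndarray] | None = None

    # -- variant transforms -------------------------------------------------
    def _transform(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if self.variant != "z_scored":
            return X
        if fit:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            self.norm_ = (mu, sd)
        assert self.norm_ is not None
        mu, sd = self.norm_
        return (X - mu) / sd

    def _select_param(self, matrix: BasePredictionMatrix,
                      X: np.ndarray, y: np.ndarray) -> float:
        """Inner-CV choice of the family's regularization parameter."""
        if len(self.param_grid) == 1:
            return float(self.param_grid[0])
        folds = matrix.frame["fold"].to_numpy() \
            if "fold" in matrix.frame.columns else \
            np.arange(len(y)) % 5
        best_param, best = float(self.param_grid[0]), np.inf
        for param in self.param_grid:
            errs = []
            for f in np.unique(folds):
                tr, te = folds != f, folds == f
                if tr.sum() == 0 or te.sum() == 0:
                    continue
                m = _make_meta(self.family, param, self.seed)
                m.fit(X[tr], y[tr])
                errs.append(float(np.mean((m.predict(X[te]) - y[te]) ** 2)))
            score = float(np.mean(errs)) if errs else np.inf
            if score < best:
                best_param, best = float(param), score
        return best_param

    # -- fitting ------------------------------------------------------------
    def fit(self, matrix: BasePredictionMatrix) -> "StackingEnsemble":
        X = self._transform(matrix.X(), fit=True)
        y = matrix.frame["truth"].to_numpy(dtype=float)
        if self.family == "linear" and np.linalg.matrix_rank(
                np.column_stack([X, np.ones(len(X))])) < X.shape[1] + 1:
            logger.info("singular design for unregularized linear stacking; "
                        "fitting via least squares pseudo-inverse")
        self.param_ = self._select_param(matrix, X, y)
        self.model_ = _make_meta(self.family, self.param_, self.seed)
        self.model_.fit(X, y)
        if self.variant == "per_subject":
            subjects = matrix.frame["subject_id"].astype(str)
            for subject in sorted(subjects.unique()):
                mask = (subjects == subject).to_numpy()
                if mask.sum() < self.min_subject_obs:
                    logger.info("subject %s has %d < %d stacking rows; "
                                "pooled fallback", subject, int(mask.sum()),
                                self.min_subject_obs)
                    continue
                if self.family == "linear" and _singular(X[mask]):
                    logger.info("singular per-subject design for %s; "
                                "pooled fallback", subject)
                    continue
                m = _make_meta(self.family, self.param_, self.seed)
                m.fit(X[mask], y[mask])
                self.subject_models_[subject] = m
        return self

    def predict(self, matrix: BasePredictionMatrix) -> pd.Series:
        assert self.model_ is not None, "fit first"
        X = self._transform(matrix.X(), fit=False)
        pred = self.model_.predict(X)
        if self.variant == "per_subject" and self.subject_models_:
            subjects = matrix.frame["subject_id"].astype(str)
            for subject, m in self.subject_models_.items():
                mask = (subjects == subject).to_numpy()
                if mask.any():
                    pred[mask] = m.predict(X[mask])
        return pd.Series(pred,
                         index=matrix.frame["measurement_id"].astype(str))

    def describe(self) -> dict:
        d = {"family": f"stacking_{self.family}", "variant": self.variant,
             "param": self.param_}
        if hasattr(self.model_, "coef_"):
            d["weights"] = [float(w) for w in np.ravel(self.model_.coef_)]
        return d


# ---------------------------------------------------------------------------
# CES: greedy forward selection with replacement
# ---------------------------------------------------------------------------

class CesEnsemble:
    """Caruana-style ensemble selection into a running average.

    Starts from the single best base by weighted MSE and repeatedly adds
    (with replacement) whichever base most improves the running-mean
    WMSE, stopping when no addition strictly improves or after
    ``max_iter`` additions.
    """

    def __init__(self, max_iter: int = 50) -> None:
        self.max_iter = max_iter
        self.members_: list[str] = []

    def fit(self, matrix: BasePredictionMatrix) -> "CesEnsemble":
        bases = matrix.base_names
        cols = {b: matrix.frame[b].to_numpy(dtype=float) for b in bases}
        best = min(bases, key=lambda b: (matrix.wmse_of(cols[b]), b))
        self.members_ = [best]
        current = cols[best].copy()
        score = matrix.wmse_of(current)
        for _ in range(self.max_iter - 1):
            trials = {}
            for b in bases:
                cand = (current * len(self.members_) + cols[b]) / (
                    len(self.members_) + 1)
                trials[b] = matrix.wmse_of(cand)
            b_best = min(bases, key=lambda b: (trials[b], b))
            if trials[b_best] >= score:
                break
            self.members_.append(b_best)
            current = (current * (len(self.members_) - 1)
                       + cols[b_best]) / len(self.members_)
            score = trials[b_best]
        return self

    def predict(self, matrix: BasePredictionMatrix) -> pd.Series:
        if not self.members_:
            raise RuntimeError("fit first")
        X = matrix.frame[self.members_].to_numpy(dtype=float)
        return pd.Series(X.mean(axis=1),
                         index=matrix.frame["measurement_id"].astype(str))

    def describe(self) -> dict:
        return {"family": "ces", "members": list(self.members_)}


def ces_select(matrix: BasePredictionMatrix,
               max_iter: int = 50) -> CesEnsemble:
    return CesEnsemble(max_iter=max_iter).fit(matrix)


# ---------------------------------------------------------------------------
# Exhaustive subset + L2-linear search
# ---------------------------------------------------------------------------

class SubsetLinearEnsemble:
    """Best ridge combination over an exhaustively enumerated base subset.

    Rows are split (within subject) into a ``learn_fraction`` part used
    to fit each subset's ridge weights and a held-out part used to score
    and pick the winning subset/alpha.  ``refit`` re-estimates the
    winning combination on a full matrix.
    """

    def __init__(self, learn_fraction: float = 0.8,
                 alpha_grid=DEFAULT_ALPHA_GRID, seed: int = 0,
                 max_bases: int = 12) -> None:
        self.learn_fraction = learn_fraction
        self.alpha_grid = tuple(alpha_grid)
        self.seed = seed
        self.max_bases = max_bases
        self.subset_: tuple[str, ...] = ()
        self.alpha_: float = 1.0
        self.model_: Ridge | None = None
        self.n_subsets_evaluated_: int = 0

    def _split(self, matrix: BasePredictionMatrix) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        subjects = matrix.frame["subject_id"].astype(str).to_numpy()
        learn = np.zeros(len(subjects), dtype=bool)
        for subject in np.unique(subjects):
            idx = np.flatnonzero(subjects == subject)
            rng.shuffle(idx)
            n_learn = max(1, int(round(self.learn_fraction * len(idx))))
            learn[idx[:n_learn]] = True
        return learn

    def fit(self, matrix: BasePredictionMatrix) -> "SubsetLinearEnsemble":
        bases = matrix.base_names
        if len(bases) > self.max_bases:
            raise ValueError(
                f"{len(bases)} bases exceed the exhaustive bound "
                f"{self.max_bases}; use CES or stacking instead")
        learn = self._split(matrix)
        hold = ~learn
        y = matrix.frame["truth"].to_numpy(dtype=float)
        X = matrix.X()
        hold_matrix = matrix.subset(hold)
        best = (np.inf, ())
        self.n_subsets_evaluated_ = 0
        for r in range(1, len(bases) + 1):
            for combo in itertools.combinations(range(len(bases)), r):
                self.n_subsets_evaluated_ += 1
                for alpha in self.alpha_grid:
                    m = Ridge(alpha=alpha)
                    m.fit(X[np.ix_(learn, combo)], y[learn])
                    pred = m.predict(X[np.ix_(hold, combo)])
                    score = hold_matrix.wmse_of(pred)
                    key = (score, tuple(bases[i] for i in combo), alpha)
                    if key[:1] < best[:1] or (
                            score == best[0] and key[1:] < best[1:]):
                        best = key
        self.subset_ = best[1]
        self.alpha_ = float(best[2])
        self.refit(matrix)
        return self

    def refit(self, matrix: BasePredictionMatrix) -> "SubsetLinearEnsemble":
        cols = list(self.subset_)
        self.model_ = Ridge(alpha=self.alpha_)
        self.model_.fit(matrix.frame[cols].to_numpy(dtype=float),
                        matrix.frame["truth"].to_numpy(dtype=float))
        return self

    def predict(self, matrix: BasePredictionMatrix) -> pd.Series:
        assert self.model_ is not None, "fit first"
        X = matrix.frame[list(self.subset_)].to_numpy(dtype=float)
        return pd.Series(self.model_.predict(X),
                         index=matrix.frame["measurement_id"].astype(str))

    def describe(self) -> dict:
        return {"family": "subset_linear", "subset": list(self.subset_),
                "alpha": self.alpha_,
                "weights": [float(w) for w in self.model_.coef_]
                if self.model_ is not None else None}


def subset_linear_select(matrix: BasePredictionMatrix,
                         learn_fraction: float = 0.8,
                         seed: int = 0) -> SubsetLinearEnsemble:
    return SubsetLinearEnsemble(learn_fraction=learn_fraction,
                                seed=seed).fit(matrix)


# ---------------------------------------------------------------------------
# Candidate zoo and final selection
# ---------------------------------------------------------------------------

def build_candidates(seed: int = 0, stacking_variants=STACKING_VARIANTS,
                     families=STACKING_FAMILIES) -> dict[str, object]:
    """The ensemble candidates entered into model selection."""
    cands: dict[str, object] = {
        "mean": UnsupervisedEnsemble("mean"),
        "median": UnsupervisedEnsemble("median"),
        "ces": CesEnsemble(),
        "subset_linear": SubsetLinearEnsemble(seed=seed),
    }
    for fam in families:
        for var in stacking_variants:
            cands[f"stacking_{fam}_{var}"] = StackingEnsemble(
                family=fam, variant=var, seed=seed)
    return cands


UNSUPERVISED = ("mean", "median")


@dataclass
class FinalEnsembles:
    """Winners of the evaluation-fold selection, refit on full training."""

    unsupervised_name: str
    supervised_name: str
    unsupervised: object
    supervised: object
    eval_wmse: dict[str, float]
    test_predictions: dict[str, pd.Series] = field(default_factory=dict)


def select_and_finalize(inner_matrix: BasePredictionMatrix,
                        eval_matrix: BasePredictionMatrix,
                        full_matrix: BasePredictionMatrix,
                        test_matrix: BasePredictionMatrix | None = None,
                        seed: int = 0) -> FinalEnsembles:
    """Fit candidates on the inner folds, pick winners on the evaluation
    fold, refit on the full training matrix, and predict the test set.

    ``inner_matrix`` holds out-of-fold base predictions on the five inner
    folds; ``eval_matrix`` holds base predictions on the untouched
    evaluation fold; ``full_matrix`` holds out-of-fold base predictions
    regenerated over the whole training set for the final refit.
    Evaluation-fold truth is used only for selection, never for fitting.
    """
    candidates = build_candidates(seed=seed)
    eval_wmse: dict[str, float] = {}
    for name, cand in candidates.items():
        cand.fit(inner_matrix)
        pred = cand.predict(eval_matrix)
        eval_wmse[name] = eval_matrix.wmse_of(pred.to_numpy())
    unsup = min(UNSUPERVISED, key=lambda n: (eval_wmse[n], n))
    supervised_names = [n for n in candidates if n not in UNSUPERVISED]
    sup = min(supervised_names, key=lambda n: (eval_wmse[n], n))
    logger.info("selected ensembles: unsupervised=%s supervised=%s",
                unsup, sup)
    final_unsup = build_candidates(seed=seed)[unsup].fit(full_matrix)
    final_sup = build_candidates(seed=seed)[sup].fit(full_matrix)
    out = FinalEnsembles(unsup, sup, final_unsup, final_sup, eval_wmse)
    if test_matrix is not None:
        out.test_predictions = {
            "unsupervised": final_unsup.predict(test_matrix),
            "supervised": final_sup.predict(test_matrix),
        }
    return out
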