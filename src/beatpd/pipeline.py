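"""End-to-end orchestration: simulate -> prepare -> featurize -> train ->
score -> ensemble -> posthoc, under a single config with full determinism.

Each stage reads only on-disk artifacts of upstream stages and writes its
outputs plus a manifest (input hashes, output hashes, stage seed).  A
rerun skips stages whose recorded input and output hashes still match the
files on disk; a stage whose upstream artifacts changed re-executes, as
does everything downstream of it.  One global seed fans out to per-stage
seeds through ``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import challenge_scoring as scoring
from . import data_model_io as dio
from . import ensemble_builder as ens
from . import feature_extraction as fx
from . import posthoc_analysis as post
from . import severity_models as models
from .synthetic_cohort import (CohortSpec, SubjectProfile, generate_cohort,
                               sample_labels, synthesize_segment)

logger = logging.getLogger("beatpd")

STAGES = ("simulate", "prepare", "featurize", "train", "score", "ensemble",
          "posthoc")
VERSION = "0.1.0"


class PipelineError(RuntimeError):
    pass


class StaleUpstreamError(PipelineError):
    """Upstream artifacts changed since their manifest was written."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Single structured configuration for a full run."""

    seed: int = 0
    output_dir: str = "run"
    symptoms: tuple[str, ...] = ("on_off", "dyskinesia", "tremor")
    cohorts: list[dict] = field(default_factory=lambda: [
        {"cohort_id": "CIS", "n_subjects": 4,
         "reports_per_subject_range": (44, 48), "segment_duration": 120.0},
    ])
    model: dict = field(default_factory=lambda: {
        "search_iterations": 2, "n_estimators": (60, 120),
        "max_depth_choices": (5, 10, None), "min_samples_leaf": (1, 5),
        "cv_folds": 5})
    scoring: dict = field(default_factory=lambda: {"B": 1000, "alpha": 0.05})
    ensemble: dict = field(default_factory=lambda: {
        "k": 6, "B_lift": 100, "base_n_estimators": 60})
    clinical: dict = field(default_factory=lambda: {
        "segments_per_subject": 12, "duration": 30.0})

    def validate(self) -> None:
        alpha = self.scoring.get("alpha", 0.05)
        if not 0 < alpha < 1:
            raise PipelineError(f"alpha={alpha} outside (0, 1)")
        if self.seed is None:
            raise PipelineError("seed must be explicit")
        if int(self.scoring.get("B", 1000)) < 1:
            raise PipelineError("scoring B must be >= 1")
        for symptom in self.symptoms:
            if symptom not in dio.SYMPTOMS:
                raise PipelineError(f"unknown symptom {symptom!r}")
        for c in self.cohorts:
            CohortSpec(**{**c, "seed": 0}).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.symptoms = tuple(cfg.symptoms)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))

    def model_spec(self, symptom: str, archetype: str,
                   seed: int) -> models.ModelSpec:
        m = self.model
        return models.ModelSpec(
            archetype=archetype, symptom=symptom,
            n_estimators=tuple(m.get("n_estimators", (100, 500))),
            max_depth_choices=tuple(m.get("max_depth_choices",
                                          (3, 5, 10, None))),
            min_samples_leaf=tuple(m.get("min_samples_leaf", (1, 20))),
            cv_folds=int(m.get("cv_folds", 5)),
            search_iterations=int(m.get("search_iterations", 25)),
            seed=seed)


def stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_dir(run_dir: Path, stage: str) -> Path:
    return run_dir / stage


def _manifest_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f"manifest_{stage}.json"


def _outputs_of(run_dir: Path, stage: str) -> list[Path]:
    d = _stage_dir(run_dir, stage)
    return sorted(p for p in d.rglob("*") if p.is_file()) if d.exists() else []


def _write_manifest(run_dir: Path, stage: str, inputs: list[Path],
                    seed: int) -> None:
    manifest = {
        "stage": stage,
        "version": VERSION,
        "seed": seed,
        "inputs": {str(p.relative_to(run_dir)): _hash_file(p)
                   for p in sorted(inputs)},
        "outputs": {str(p.relative_to(run_dir)): _hash_file(p)
                    for p in _outputs_of(run_dir, stage)},
    }
    _manifest_path(run_dir, stage).write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


def _manifest_current(run_dir: Path, stage: str) -> bool:
    """True when the stage's recorded inputs and outputs match the disk."""
    mpath = _manifest_path(run_dir, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    for rel, digest in {**manifest["inputs"], **manifest["outputs"]}.items():
        p = run_dir / rel
        if not p.exists() or _hash_file(p) != digest:
            return False
    return True


def _check_upstream(run_dir: Path, stage: str) -> None:
    idx = STAGES.index(stage)
    if idx == 0:
        return
    upstream = STAGES[idx - 1]
    mpath = _manifest_path(run_dir, upstream)
    if not mpath.exists():
        raise PipelineError(
            f"stage {stage!r} needs upstream stage {upstream!r}; "
            f"run it first (stages: {', '.join(STAGES)})")
    manifest = json.loads(mpath.read_text())
    for rel, digest in manifest["outputs"].items():
        p = run_dir / rel
        if not p.exists() or _hash_file(p) != digest:
            raise StaleUpstreamError(
                f"upstream artifact {rel} is missing or changed since "
                f"stage {upstream!r} ran; rerun {upstream!r} first")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    out = _stage_dir(run_dir, "simulate")
    for i, ckw in enumerate(cfg.cohorts):
        spec = CohortSpec(**{**ckw, "seed": seed + i})
        cohort = generate_cohort(spec)
        cohort.write(out)
        profiles = [_profile_to_dict(p) for p in cohort.profiles]
        (out / f"profiles_{spec.cohort_id}.json").write_text(
            json.dumps(profiles, indent=2, sort_keys=True))
        (out / f"spec_{spec.cohort_id}.json").write_text(
            json.dumps(dataclasses.asdict(spec), indent=2, sort_keys=True,
                       default=list))
        # Internal harmonized label columns, needed only by the clinical
        # validation synthesiser, are persisted separately.
        cohort.labels.to_csv(out / f"labels_internal_{spec.cohort_id}.csv",
                             index=False)
    return []


def _profile_to_dict(p: SubjectProfile) -> dict:
    d = dataclasses.asdict(p)
    for key in ("updrs_part3_items_on", "updrs_part3_items_off",
                "updrs_part4_items", "tremor_direction"):
        d[key] = [float(v) for v in d[key]]
    return d


def _profile_from_dict(d: dict) -> SubjectProfile:
    d = dict(d)
    for key in ("updrs_part3_items_on", "updrs_part3_items_off",
                "updrs_part4_items", "tremor_direction"):
        d[key] = np.asarray(d[key])
    return SubjectProfile(**d)


def _cohort_ids(cfg: RunConfig) -> list[str]:
    return [c["cohort_id"] for c in cfg.cohorts]


def _stage_prepare(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    sim = _stage_dir(run_dir, "simulate")
    out = _stage_dir(run_dir, "prepare")
    out.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    frames = []
    for cid in _cohort_ids(cfg):
        path = sim / f"labels_{cid}.csv"
        inputs.append(path)
        raw = dio.read_labels(path)
        raw["reporting_lag"] = (raw["timestamp_report"]
                                - raw["timestamp_slot"]) / 60.0
        frames.append(dio.harmonize_table(cid, raw))
    labels = pd.concat(frames, ignore_index=True)
    labels.to_csv(out / "labels_harmonized.csv", index=False)

    # Activity filter over every segment file.
    retained = []
    for cid in _cohort_ids(cfg):
        meta = labels[labels["cohort_id"] == cid].set_index("measurement_id")
        for path in sorted((sim / "segments").glob("*.csv")):
            stem = path.stem
            device = "watch"
            if stem.endswith("_phone"):
                stem, device = stem[:-6], "phone"
            if stem not in meta.index:
                continue
            seg = dio.read_segment(path, subject_id=str(
                meta.loc[stem, "subject_id"]), cohort_id=cid, device=device)
            inputs.append(path)
            if dio.activity_duration(seg) >= 120:
                retained.append((stem, device, str(path.relative_to(run_dir)),
                                 seg.subject_id, cid))
            else:
                logger.info("activity filter removed %s (%s)", stem, device)
    pd.DataFrame(retained, columns=["measurement_id", "device", "path",
                                    "subject_id", "cohort_id"]) \
        .to_csv(out / "retained_segments.csv", index=False)

    eligibility = {s: sorted(dio.filter_subjects(labels, s))
                   for s in cfg.symptoms}
    (out / "eligibility.json").write_text(
        json.dumps(eligibility, indent=2, sort_keys=True))

    eligible_any = sorted(set().union(*eligibility.values())) \
        if eligibility else []
    split_labels = labels[labels["subject_id"].astype(str).isin(eligible_any)]
    split = dio.split_train_test(split_labels, ratio=0.75, seed=seed)
    dio.write_split(split, out / "split.csv")
    return inputs


def _read_prepare(run_dir: Path):
    prep = _stage_dir(run_dir, "prepare")
    labels = pd.read_csv(prep / "labels_harmonized.csv")
    labels["measurement_id"] = labels["measurement_id"].astype(str)
    labels["subject_id"] = labels["subject_id"].astype(str)
    retained = pd.read_csv(prep / "retained_segments.csv")
    retained["measurement_id"] = retained["measurement_id"].astype(str)
    eligibility = json.loads((prep / "eligibility.json").read_text())
    split = dio.read_split(prep / "split.csv")
    return labels, retained, eligibility, split


def _stage_featurize(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    prep = _stage_dir(run_dir, "prepare")
    out = _stage_dir(run_dir, "featurize")
    out.mkdir(parents=True, exist_ok=True)
    labels, retained, _, _ = _read_prepare(run_dir)
    inputs = [prep / "labels_harmonized.csv", prep / "retained_segments.csv"]
    segments = []
    for row in retained.itertuples():
        path = run_dir / row.path
        inputs.append(path)
        segments.append(dio.read_segment(path, subject_id=str(row.subject_id),
                                         cohort_id=str(row.cohort_id),
                                         device=str(row.device)))
    fs_by_cohort = {c["cohort_id"]: float(c.get("sampling_rate", 50.0))
                    for c in cfg.cohorts}
    for feature_set in ("generic", "actigraphy"):
        tables = []
        for cid, fs in fs_by_cohort.items():
            cohort_segments = [s for s in segments if s.cohort_id == cid]
            if cohort_segments:
                tables.append(fx.extract_features(
                    cohort_segments, feature_set=feature_set,
                    sampling_rate=fs))
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out / f"features_{feature_set}.csv", index=False)
    return inputs


def _designs(cfg: RunConfig, run_dir: Path):
    """Window-level design matrices for both archetypes."""
    feat_dir = _stage_dir(run_dir, "featurize")
    sim = _stage_dir(run_dir, "simulate")
    labels, retained, eligibility, split = _read_prepare(run_dir)
    generic = pd.read_csv(feat_dir / "features_generic.csv")
    actig = pd.read_csv(feat_dir / "features_actigraphy.csv")
    for df in (generic, actig):
        df["measurement_id"] = df["measurement_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
    covs = pd.concat([pd.read_csv(sim / f"covariates_{cid}.csv")
                      for cid in _cohort_ids(cfg)], ignore_index=True)
    design_ps = fx.assemble_design_matrix(generic, labels,
                                          mode="sensor_only")
    design_gl = fx.assemble_design_matrix(actig, labels, covariates=covs,
                                          mode="with_covariates")
    return labels, eligibility, split, design_ps, design_gl, covs


def _partition_design(design: pd.DataFrame, split: dio.SplitAssignment,
                      subjects: list[str], partition: str) -> pd.DataFrame:
    ids = set(split.ids(partition))
    mask = design["measurement_id"].isin(ids) \
        & design["subject_id"].isin(subjects)
    return design[mask].reset_index(drop=True)


def _stage_train(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    import joblib

    out = _stage_dir(run_dir, "train")
    out.mkdir(parents=True, exist_ok=True)
    labels, eligibility, split, design_ps, design_gl, _ = _designs(cfg, run_dir)
    inputs = [_stage_dir(run_dir, "featurize") / "features_generic.csv",
              _stage_dir(run_dir, "featurize") / "features_actigraphy.csv",
              _stage_dir(run_dir, "prepare") / "split.csv"]
    for symptom in cfg.symptoms:
        subjects = eligibility[symptom]
        if not subjects:
            logger.warning("no eligible subjects for %s", symptom)
            continue
        obs = labels.dropna(subset=[symptom])
        obs = obs[obs["subject_id"].isin(subjects)]
        train_ids = set(split.ids("train"))
        train_obs = obs[obs["measurement_id"].isin(train_ids)]
        test_obs = obs[~obs["measurement_id"].isin(train_ids)]

        null = models.fit_null(train_obs, symptom)
        tr_ps = _partition_design(design_ps.dropna(subset=[symptom]),
                                  split, subjects, "train")
        te_ps = _partition_design(design_ps.dropna(subset=[symptom]),
                                  split, subjects, "test")
        tr_gl = _partition_design(design_gl.dropna(subset=[symptom]),
                                  split, subjects, "train")
        te_gl = _partition_design(design_gl.dropna(subset=[symptom]),
                                  split, subjects, "test")

        ps = models.fit_per_subject(tr_ps, symptom,
                                    cfg.model_spec(symptom, "per_subject",
                                                   seed))
        gl = models.fit_global(tr_gl, symptom,
                               cfg.model_spec(symptom, "global", seed + 1))
        preds = {
            "Null": null.predict(test_obs),
            "per_subject": models.predict_observation(
                ps, te_ps.rename(columns={symptom: "label"}), null),
            "global": models.predict_observation(
                gl, te_gl.rename(columns={symptom: "label"}), null),
        }
        # Completeness: observations whose windows were all dropped still
        # need a prediction (Null fallback); missing values are not allowed.
        preds = {name: _complete(series, test_obs, null)
                 for name, series in preds.items()}
        for name, series in preds.items():
            df = pd.DataFrame({"measurement_id": series.index,
                               "prediction": series.to_numpy()})
            df.sort_values("measurement_id").to_csv(
                out / f"predictions_{name}_{symptom}.csv", index=False)
        joblib.dump({"null": null, "per_subject": ps, "global": gl},
                    out / f"models_{symptom}.joblib")
        card = {
            "symptom": symptom,
            "seed": seed,
            "per_subject_importance": _importance_dict(ps),
            "global_importance": {
                c: _importance_dict(m) for c, m in gl.items()},
        }
        (out / f"model_card_{symptom}.json").write_text(
            json.dumps(card, indent=2, sort_keys=True))
    return inputs


def _complete(series: pd.Series, observations: pd.DataFrame,
              null: models.NullModel) -> pd.Series:
    """Fill predictions for observations absent from a series with the
    subject's Null prediction."""
    out = {}
    for row in observations.itertuples():
        mid = str(row.measurement_id)
        if mid in series.index:
            out[mid] = float(series.loc[mid])
        else:
            logger.info("prediction missing for %s; Null fallback", mid)
            out[mid] = null.predict_subject(str(row.subject_id))
    return pd.Series(out).sort_index()


def _importance_dict(model) -> dict[str, float]:
    imp = model.feature_importance()
    return {str(k): float(v) for k, v in imp.items()}


def _truth_table(labels: pd.DataFrame, split: dio.SplitAssignment,
                 symptom: str, subjects: list[str]) -> pd.DataFrame:
    test_ids = set(split.ids("test"))
    obs = labels.dropna(subset=[symptom])
    obs = obs[obs["subject_id"].isin(subjects)
              & obs["measurement_id"].isin(test_ids)]
    return pd.DataFrame({"measurement_id": obs["measurement_id"],
                         "subject_id": obs["subject_id"],
                         "label": obs[symptom].astype(float)})


def _read_predictions(run_dir: Path, stage: str, name: str,
                      symptom: str) -> pd.Series:
    path = _stage_dir(run_dir, stage) / f"predictions_{name}_{symptom}.csv"
    df = pd.read_csv(path)
    return pd.Series(df["prediction"].to_numpy(),
                     index=df["measurement_id"].astype(str))


def _stage_score(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    out = _stage_dir(run_dir, "score")
    out.mkdir(parents=True, exist_ok=True)
    labels, _, eligibility, split = _read_prepare(run_dir)
    inputs = []
    B = int(cfg.scoring.get("B", 1000))
    alpha = float(cfg.scoring.get("alpha", 0.05))
    for symptom in cfg.symptoms:
        subjects = eligibility[symptom]
        if not subjects:
            continue
        truth = _truth_table(labels, split, symptom, subjects)
        preds = {}
        for name in ("Null", "per_subject", "global"):
            path = _stage_dir(run_dir, "train") \
                / f"predictions_{name}_{symptom}.csv"
            inputs.append(path)
            preds[name] = _read_predictions(run_dir, "train", name, symptom)
        board = scoring.leaderboard(preds, truth, B=B, seed=seed,
                                    alpha=alpha)
        board.to_csv(out / f"leaderboard_{symptom}.csv", index=False)
        for name in ("per_subject", "global", "Null"):
            table = scoring.score_predictions(preds[name], truth)
            p = board.loc[board["submission_id"] == name,
                          "p_vs_null"].iloc[0]
            scoring.write_score_report(
                table, name, out / f"score_{name}_{symptom}.json",
                p_vs_null=None if pd.isna(p) else float(p), B=B, seed=seed)
    return inputs


# -- ensemble stage ---------------------------------------------------------

def _base_model_configs(cfg: RunConfig, seed: int) -> list[str]:
    """Five deliberately heterogeneous base model configurations standing
    in for the distinct teams whose predictions fed the ensembles."""
    return ["per_subject_rf", "global_rf", "global_gbrt", "null",
            "null_noise"]


def _fit_predict_base(name: str, symptom: str, cfg: RunConfig, seed: int,
                      train_ps: pd.DataFrame, train_gl: pd.DataFrame,
                      train_obs: pd.DataFrame,
                      predict_sets: list) -> list[pd.Series]:
    """Train one base model and predict each held-out observation set.

    ``predict_sets`` is a list of ``(ps_rows, gl_rows, obs_frame)``
    tuples; one prediction series is returned per set, all from the same
    fitted model.
    """
    null = models.fit_null(train_obs, symptom)
    n_est = int(cfg.ensemble.get("base_n_estimators", 60))
    base_spec = models.ModelSpec(
        symptom=symptom, n_estimators=(n_est, n_est),
        max_depth_choices=(8,), min_samples_leaf=(2, 2),
        search_iterations=1, seed=seed)
    if name == "per_subject_rf":
        spec = dataclasses.replace(base_spec, archetype="per_subject")
        model = models.fit_per_subject(train_ps, symptom, spec)
        return [models.predict_observation(
            model, ps.rename(columns={symptom: "label"}), null)
            for ps, _, _ in predict_sets]
    if name == "global_rf":
        spec = dataclasses.replace(base_spec, archetype="global")
        model = models.fit_global(train_gl, symptom, spec)
        return [models.predict_observation(
            model, gl.rename(columns={symptom: "label"}), null)
            for _, gl, _ in predict_sets]
    if name == "global_gbrt":
        from sklearn.ensemble import GradientBoostingRegressor

        df = train_gl.rename(columns={symptom: "label"}) \
            .dropna(subset=["label"])
        cols = models.feature_columns(df)
        gbrt = GradientBoostingRegressor(random_state=seed)
        gbrt.fit(df[cols].to_numpy(dtype=float),
                 df["label"].to_numpy(dtype=float))
        out = []
        for _, gl, _ in predict_sets:
            pdf = gl.rename(columns={symptom: "label"})
            window_preds = pd.DataFrame({
                "measurement_id": pdf["measurement_id"].astype(str),
                "device": pdf["device"] if "device" in pdf else "watch",
                "pred": gbrt.predict(pdf[cols].to_numpy(dtype=float))})
            obs = models._aggregate(window_preds, "mean")
            meta = pdf[["measurement_id", "cohort_id"]].drop_duplicates()
            out.append(models._clip_to_range(obs, meta, symptom))
        return out
    if name == "null":
        return [null.predict(obs) for _, _, obs in predict_sets]
    if name == "null_noise":
        # Null predictions plus seeded noise: a weak, deliberately
        # different fifth base.
        rng = np.random.default_rng(seed)
        out = []
        for _, _, obs in predict_sets:
            pred = null.predict(obs)
            out.append(pred + rng.normal(0, 0.3, size=len(pred)))
        return out
    raise PipelineError(f"unknown base model {name!r}")


def _build_base_matrices(cfg: RunConfig, run_dir: Path, seed: int,
                         symptom: str):
    """Out-of-fold base prediction matrices for the nested-CV protocol.

    The inner matrix holds out-of-fold predictions over the five inner
    folds.  The evaluation- and test-matrix meta-features are the
    averages of the corresponding fold models' predictions, so that the
    meta-learners see the same input distribution at selection and test
    time as they saw in their out-of-fold training rows.
    """
    labels, eligibility, split, design_ps, design_gl, _ = _designs(cfg, run_dir)
    subjects = eligibility[symptom]
    k = int(cfg.ensemble.get("k", 6))
    obs = labels.dropna(subset=[symptom])
    obs = obs[obs["subject_id"].isin(subjects)]
    train_ids = set(split.ids("train"))
    train_obs = obs[obs["measurement_id"].isin(train_ids)].copy()
    test_obs = obs[~obs["measurement_id"].isin(train_ids)].copy()
    train_obs["label"] = train_obs[symptom].astype(float)
    folds = ens.nested_cv(train_obs, k=k, seed=seed)
    train_obs["fold"] = folds.loc[train_obs["measurement_id"]].to_numpy()

    dps = design_ps.dropna(subset=[symptom])
    dps = dps[dps["subject_id"].isin(subjects)]
    dgl = design_gl.dropna(subset=[symptom])
    dgl = dgl[dgl["subject_id"].isin(subjects)]
    fold_of = dict(zip(train_obs["measurement_id"], train_obs["fold"]))
    truth_src = pd.concat([train_obs, test_obs.assign(
        label=test_obs[symptom].astype(float))])
    truth_map = dict(zip(truth_src["measurement_id"], truth_src["label"]))

    def rows_for(ids: set[str], design: pd.DataFrame) -> pd.DataFrame:
        return design[design["measurement_id"].isin(ids)].reset_index(drop=True)

    def obs_frame(ids: set[str]) -> pd.DataFrame:
        sel = train_obs[train_obs["measurement_id"].isin(ids)]
        return sel if not sel.empty else test_obs[
            test_obs["measurement_id"].isin(ids)]

    def predict_set(ids: set[str]):
        return (rows_for(ids, dps), rows_for(ids, dgl), obs_frame(ids))

    def base_frame(ids: set[str]) -> pd.DataFrame:
        frame = obs_frame(ids)[["measurement_id", "subject_id"]].copy()
        frame["truth"] = frame["measurement_id"].map(truth_map)
        return frame

    bases = _base_model_configs(cfg, seed)
    eval_fold = k - 1
    inner_folds = list(range(k - 1))

    def run_cv(cv_folds: list[int], exclude: set[int], held_ids: set[str],
               base_seed: int):
        """Per fold: train bases on the remaining folds, predict the fold
        out-of-fold and the held-out set; held-out meta-features are the
        across-fold means."""
        oof_parts = []
        held = base_frame(held_ids)
        held_sums = {b: np.zeros(len(held)) for b in bases}
        for f in cv_folds:
            tr = {m for m, fl in fold_of.items()
                  if fl != f and fl not in exclude}
            pr = {m for m, fl in fold_of.items() if fl == f}
            tr_o = train_obs[train_obs["measurement_id"].isin(tr)]
            null_fallback = models.fit_null(tr_o, symptom)
            part = base_frame(pr)
            for b_i, b in enumerate(bases):
                oof_pred, held_pred = _fit_predict_base(
                    b, symptom, cfg, base_seed + 10 * f + b_i,
                    rows_for(tr, dps), rows_for(tr, dgl), tr_o,
                    [predict_set(pr), predict_set(held_ids)])
                oof_pred = _complete(oof_pred, obs_frame(pr), null_fallback)
                held_pred = _complete(held_pred, obs_frame(held_ids),
                                      null_fallback)
                part[b] = part["measurement_id"].map(oof_pred.to_dict())
                held_sums[b] += held["measurement_id"].map(
                    held_pred.to_dict()).to_numpy(dtype=float)
            part["fold"] = f
            oof_parts.append(part)
        for b in bases:
            held[b] = held_sums[b] / len(cv_folds)
        oof = pd.concat(oof_parts, ignore_index=True)
        return oof, held

    # Inner CV: evaluation fold never used to train; its meta-features
    # are the mean of the five inner fold models' predictions.
    eval_ids = {m for m, fl in fold_of.items() if fl == eval_fold}
    inner, eval_frame = run_cv(inner_folds, {eval_fold}, eval_ids,
                               seed + 100)
    eval_frame["fold"] = eval_fold

    # Full-training CV for the final refit; test meta-features are the
    # mean of the six fold models' predictions.
    test_ids = set(test_obs["measurement_id"])
    full, test_frame = run_cv(list(range(k)), set(), test_ids, seed + 300)
    test_frame["fold"] = -1

    to_matrix = ens.matrix_from_frame
    return (to_matrix(inner.sort_values("measurement_id")
                      .reset_index(drop=True)),
            to_matrix(eval_frame.sort_values("measurement_id")
                      .reset_index(drop=True)),
            to_matrix(full.sort_values("measurement_id")
                      .reset_index(drop=True)),
            to_matrix(test_frame.sort_values("measurement_id")
                      .reset_index(drop=True)))


def _stage_ensemble(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    out = _stage_dir(run_dir, "ensemble")
    out.mkdir(parents=True, exist_ok=True)
    _, _, eligibility, _ = _read_prepare(run_dir)
    inputs = [_stage_dir(run_dir, "featurize") / "features_generic.csv",
              _stage_dir(run_dir, "featurize") / "features_actigraphy.csv"]
    for symptom in cfg.symptoms:
        if not eligibility[symptom]:
            continue
        inner, eval_m, full, test = _build_base_matrices(
            cfg, run_dir, seed, symptom)
        final = ens.select_and_finalize(inner, eval_m, full, test, seed=seed)
        full.frame.to_csv(out / f"base_matrix_{symptom}.csv", index=False)
        for kind, series in final.test_predictions.items():
            pd.DataFrame({"measurement_id": series.index,
                          "prediction": series.to_numpy()}) \
                .sort_values("measurement_id") \
                .to_csv(out / f"predictions_ensemble_{kind}_{symptom}.csv",
                        index=False)
        report = {
            "symptom": symptom,
            "unsupervised": final.unsupervised_name,
            "supervised": final.supervised_name,
            "eval_wmse": {k_: float(v)
                          for k_, v in sorted(final.eval_wmse.items())},
            "supervised_detail": final.supervised.describe(),
            "test_wmse": {
                kind: float(test.wmse_of(series.to_numpy()))
                for kind, series in sorted(final.test_predictions.items())},
            "base_test_wmse": {
                b: float(test.wmse_of(test.frame[b].to_numpy()))
                for b in test.base_names},
        }
        (out / f"ensemble_report_{symptom}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return inputs


# -- posthoc stage ----------------------------------------------------------

def _clinical_exercise(cfg: RunConfig, run_dir: Path, seed: int,
                       symptom: str) -> dict:
    """Apply the trained per-subject models to short clinician-rated task
    segments synthesised for the first cohort's subjects."""
    import joblib

    sim = _stage_dir(run_dir, "simulate")
    cid = _cohort_ids(cfg)[0]
    spec_kw = json.loads((sim / f"spec_{cid}.json").read_text())
    spec_kw["segment_duration"] = float(cfg.clinical.get("duration", 30.0))
    spec_kw["missingness_rate"] = 0.0
    spec_kw["reports_per_subject_range"] = tuple(
        spec_kw["reports_per_subject_range"])
    spec = CohortSpec(**spec_kw)
    profiles = [_profile_from_dict(d) for d in json.loads(
        (sim / f"profiles_{cid}.json").read_text())]
    bundle = joblib.load(_stage_dir(run_dir, "train")
                         / f"models_{symptom}.joblib")
    model, null = bundle["per_subject"], bundle["null"]
    m = int(cfg.clinical.get("segments_per_subject", 12))
    rng_root = np.random.SeedSequence([seed, 77])
    pred_rows, rating_rows = [], []
    for profile, ss in zip(profiles, rng_root.spawn(len(profiles))):
        if profile.subject_id not in null.means_:
            continue
        rng = np.random.default_rng(ss)
        labels = sample_labels(profile, m, rng, spec)
        segs, ratings = [], []
        for _, row in labels.iterrows():
            mid = f"clin-{profile.subject_id}-{int(row.name):03d}"
            segs.append(synthesize_segment(profile, row, spec, rng,
                                           measurement_id=mid))
            tremor_eff = float(row["_tremor_h"]) * (
                1.0 if row["_off"] else spec.onoff_attenuation)
            rating = {"tremor": float(row["_tremor_h"]),
                      "dyskinesia": float(row["_dysk_h"]),
                      # overall severity surrogate for on/off
                      "on_off": float(np.round(tremor_eff))}[symptom]
            ratings.append((mid, profile.subject_id, rating))
        feats = fx.extract_features(segs, feature_set="generic",
                                    sampling_rate=spec.sampling_rate)
        feats["cohort_id"] = cid
        pred = model.predict(feats, null_model=null)
        for mid, value in pred.items():
            pred_rows.append((mid, profile.subject_id, float(value)))
        rating_rows.extend(ratings)
    predictions = pd.DataFrame(pred_rows,
                               columns=["segment_id", "subject_id", "value"])
    ratings_df = pd.DataFrame(rating_rows,
                              columns=["segment_id", "subject_id", "value"])
    return post.clinical_validation(predictions, ratings_df)


def _stage_posthoc(cfg: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    out = _stage_dir(run_dir, "posthoc")
    out.mkdir(parents=True, exist_ok=True)
    labels, _, eligibility, split = _read_prepare(run_dir)
    sim = _stage_dir(run_dir, "simulate")
    covs = pd.concat([pd.read_csv(sim / f"covariates_{cid}.csv")
                      for cid in _cohort_ids(cfg)], ignore_index=True)
    B_lift = int(cfg.ensemble.get("B_lift", 100))
    inputs = [_stage_dir(run_dir, "prepare") / "labels_harmonized.csv"]
    for symptom in cfg.symptoms:
        subjects = eligibility[symptom]
        if not subjects:
            continue
        truth = _truth_table(labels, split, symptom, subjects)
        null_pred = _read_predictions(run_dir, "train", "Null", symptom)
        records = []
        for name in ("per_subject", "global"):
            path = _stage_dir(run_dir, "train") \
                / f"predictions_{name}_{symptom}.csv"
            inputs.append(path)
            pred = _read_predictions(run_dir, "train", name, symptom)
            records.extend(post.bootstrap_lift(
                pred, null_pred, truth, model=name, B=B_lift, seed=seed))
        lift_df = pd.DataFrame(
            [{"subject_id": r.subject_id, "model": r.model, "lift": r.lift,
              "lift_percent": r.lift_percent,
              "significant": bool(r.significant)} for r in records])
        lift_df.to_csv(out / f"lift_{symptom}.csv", index=False)
        cov_table = post.subject_covariate_table(
            labels[labels["subject_id"].isin(subjects)], covs,
            split.test_counts(), symptom)
        assoc = post.covariate_association_suite(records, cov_table)
        assoc.to_csv(out / f"associations_{symptom}.csv", index=False)
        clin = _clinical_exercise(cfg, run_dir, seed, symptom)
        (out / f"clinical_validation_{symptom}.json").write_text(
            json.dumps(clin, indent=2, sort_keys=True, default=float))
    return inputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prepare": _stage_prepare,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "score": _stage_score,
    "ensemble": _stage_ensemble,
    "posthoc": _stage_posthoc,
}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_stage(name: str, cfg: RunConfig, check_upstream: bool = True) -> Path:
    """Execute one stage and write its manifest."""
    if name not in _STAGE_FUNCS:
        raise PipelineError(
            f"unknown stage {name!r}; stages are: {', '.join(STAGES)}")
    cfg.validate()
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if check_upstream:
        _check_upstream(run_dir, name)
    seed = stage_seed(cfg.seed, name)
    logger.info("running stage %s (seed %d)", name, seed)
    stage_out = _stage_dir(run_dir, name)
    stage_out.mkdir(parents=True, exist_ok=True)
    inputs = _STAGE_FUNCS[name](cfg, run_dir, seed)
    _write_manifest(run_dir, name, inputs, seed)
    return stage_out


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    """Run every stage, skipping those whose artifacts are current.

    Once a stage re-executes, everything downstream re-executes too.
    Returns a summary report (also written to ``report.json``).
    """
    cfg.validate()
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    dirty = force
    executed = []
    for name in STAGES:
        if not dirty and _manifest_current(run_dir, name):
            logger.info("stage %s is current; skipping", name)
            continue
        dirty = True
        run_stage(name, cfg, check_upstream=False)
        executed.append(name)
    report = _final_report(cfg, run_dir, executed)
    (run_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report


# ---------------------------------------------------------------------------
# In-memory experiment (no disk artifacts)
# ---------------------------------------------------------------------------

def experiment_single_cohort(spec: CohortSpec, symptom: str,
                             archetypes: tuple[str, ...] = ("per_subject",),
                             model_spec_kwargs: dict | None = None,
                             B: int = 250, split_seed: int = 0,
                             boot_seed: int = 0) -> dict:
    """Generate one cohort, run the preparation/feature/model/scoring path
    in memory, and return WMSEs and bootstrap p-values versus Null.

    This is the single-symptom analogue of the staged pipeline, used for
    replicated simulation studies where disk artifacts are unnecessary.
    """
    cohort = generate_cohort(spec)
    raw = cohort.labels[[c for c in cohort.labels.columns
                         if not c.startswith("_")]].copy()
    raw["reporting_lag"] = (raw["timestamp_report"]
                            - raw["timestamp_slot"]) / 60.0
    labels = dio.harmonize_table(spec.cohort_id, raw)
    segments = dio.filter_segments(cohort.segments)
    eligible = sorted(dio.filter_subjects(labels, symptom))
    if not eligible:
        raise PipelineError("no eligible subjects under this configuration")
    labels = labels[labels["subject_id"].isin(eligible)]
    split = dio.split_train_test(labels, ratio=0.75, seed=split_seed)
    train_ids, test_ids = set(split.ids("train")), set(split.ids("test"))
    obs = labels.dropna(subset=[symptom])
    train_obs = obs[obs["measurement_id"].isin(train_ids)]
    test_obs = obs[obs["measurement_id"].isin(test_ids)]
    null = models.fit_null(train_obs, symptom)
    mk = dict(model_spec_kwargs or {})

    preds: dict[str, pd.Series] = {"Null": null.predict(test_obs)}
    if "per_subject" in archetypes or "global" in archetypes:
        generic = fx.extract_features(segments, "generic",
                                      sampling_rate=spec.sampling_rate)
        design = fx.assemble_design_matrix(generic, labels,
                                           mode="sensor_only")
        design = design.dropna(subset=[symptom])
        design = design[design["subject_id"].isin(eligible)]
        tr = design[design["measurement_id"].isin(train_ids)]
        te = design[design["measurement_id"].isin(test_ids)]
        if "per_subject" in archetypes:
            ps_spec = models.ModelSpec(archetype="per_subject",
                                       symptom=symptom, **mk)
            ps = models.fit_per_subject(tr, symptom, ps_spec)
            preds["per_subject"] = _complete(
                models.predict_observation(
                    ps, te.rename(columns={symptom: "label"}), null),
                test_obs, null)
        if "global" in archetypes:
            actig = fx.extract_features(segments, "actigraphy",
                                        sampling_rate=spec.sampling_rate)
            gl_design = fx.assemble_design_matrix(
                actig, labels, covariates=cohort.covariates(),
                mode="with_covariates").dropna(subset=[symptom])
            gl_design = gl_design[gl_design["subject_id"].isin(eligible)]
            gl_spec = models.ModelSpec(archetype="global", symptom=symptom,
                                       **mk)
            gl = models.fit_global(
                gl_design[gl_design["measurement_id"].isin(train_ids)],
                symptom, gl_spec)
            preds["global"] = _complete(
                models.predict_observation(
                    gl, gl_design[gl_design["measurement_id"].isin(test_ids)]
                    .rename(columns={symptom: "label"}), null),
                test_obs, null)

    truth = pd.DataFrame({"measurement_id": test_obs["measurement_id"],
                          "subject_id": test_obs["subject_id"],
                          "label": test_obs[symptom].astype(float)})
    result = scoring.bootstrap_scores(preds, truth, B=B, seed=boot_seed)
    return {
        "wmse": dict(result.point_wmse),
        "p_vs_null": {m: scoring.pvalue_vs_null(result, m)
                      for m in preds if m != "Null"},
        "n_test": len(test_obs),
        "truth": truth,
        "predictions": preds,
        "bootstrap": result,
    }


def _final_report(cfg: RunConfig, run_dir: Path, executed: list[str]) -> dict:
    config = cfg.to_dict()
    config.pop("output_dir", None)  # location-independent reports
    report: dict = {"config": config, "stages_executed": executed,
                    "symptoms": {}}
    for symptom in cfg.symptoms:
        entry: dict = {}
        lb_path = _stage_dir(run_dir, "score") / f"leaderboard_{symptom}.csv"
        if lb_path.exists():
            board = pd.read_csv(lb_path)
            entry["leaderboard"] = board.to_dict(orient="records")
        ens_path = _stage_dir(run_dir, "ensemble") \
            / f"ensemble_report_{symptom}.json"
        if ens_path.exists():
            entry["ensemble"] = json.loads(ens_path.read_text())
        clin_path = _stage_dir(run_dir, "posthoc") \
            / f"clinical_validation_{symptom}.json"
        if clin_path.exists():
            entry["clinical_validation"] = json.loads(clin_path.read_text())
        lift_path = _stage_dir(run_dir, "posthoc") / f"lift_{symptom}.csv"
        if lift_path.exists():
            lift = pd.read_csv(lift_path)
            entry["significant_lift_subjects"] = {
                str(m): int(g["significant"].sum())
                for m, g in lift.groupby("model")}
        report["symptoms"][symptom] = entry
    return report
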