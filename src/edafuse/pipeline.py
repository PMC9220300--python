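"""End-to-end orchestration: simulate → preprocess → features → embed → classify.

The central entry point is :func:`run_loso` which evaluates either the
statistical-feature-only model (SF) or the graph-embedding fusion model
(SF-GARG) under leave-one-subject-out cross-validation, and
:func:`run_pipeline` which drives the same computation from on-disk CSV
bundles, writing intermediate artifacts and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvalReport, FoldResult, compute_metrics, loso_folds
from .features import build_feature_matrix
from .fusion import FusionMLPClassifier, reduce_dim
from .garg import GargEmbedder
from .preprocessing import PreprocessConfig, preprocess_trials
from .records import EMOTIONS
from .simulate import DatasetBundle, read_bundle

__all__ = ["PipelineConfig", "run_loso", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    data_dir: str = "."
    out_dir: str = "out"
    dataset_style: str = "pafew"
    task: str = "arousal"
    mode: str = "sf-garg"          # "sf" or "sf-garg"
    fusion_style: str = "weighted"  # "weighted" (F = S ⊗ PĜ) or "concat"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embed_dim: int = 16
    embed_epochs: int = 300
    embed_negatives: int = 10
    embed_lambda: float = 1e-3
    mlp_epochs: int = 150
    mlp_lr: float = 1e-3
    mlp_loss: str = "mse"
    seed: int = 0


def _task_labels(bundle: DatasetBundle, task: str) -> pd.Series:
    if task not in ("valence", "arousal"):
        raise ValueError(f"task must be 'valence' or 'arousal', got {task!r}")
    lab = bundle.labels.set_index(["subject_id", "trial_id"])[task]
    return lab


def run_loso(
    bundle: DatasetBundle,
    task: str = "arousal",
    mode: str = "sf-garg",
    fusion_style: str = "weighted",
    preprocess: PreprocessConfig | None = None,
    embed_dim: int = 16,
    embed_epochs: int = 300,
    embed_negatives: int = 10,
    embed_lambda: float = 1e-3,
    mlp_epochs: int = 150,
    mlp_lr: float = 1e-3,
    mlp_loss: str = "mse",
    seed: int = 0,
    labels: pd.Series | None = None,
) -> EvalReport:
    """Leave-one-subject-out evaluation of SF or SF-GARG on a dataset bundle.

    The graph embedding is trained once on the full gender/age graph (it
    uses covariates only, never labels); PCA reduction and feature
    standardization are refitted inside every fold on training subjects
    only. ``labels`` overrides the bundle's task labels (used e.g. for
    permutation/null calibration).
    """
    if mode not in ("sf", "sf-garg"):
        raise ValueError(f"mode must be 'sf' or 'sf-garg', got {mode!r}")
    cfg = preprocess or PreprocessConfig()
    trials = preprocess_trials(bundle.recordings, cfg, dataset_style="pafew")
    S = build_feature_matrix(trials, dataset_style="pafew")
    y = (labels if labels is not None else _task_labels(bundle, task)).reindex(S.index)
    subject_of_row = S.index.get_level_values("subject_id")

    G = None
    if mode == "sf-garg":
        embedder = GargEmbedder(dim=embed_dim, n_negatives=embed_negatives,
                                lam=embed_lambda, epochs=embed_epochs, seed=seed)
        embedder.fit(bundle.subjects)
        G = pd.DataFrame(
            embedder.transform(bundle.subjects),
            index=[s.subject_id for s in bundle.subjects],
        )

    d = S.shape[1]
    report = EvalReport()
    for train_subjects, test_subject in loso_folds([s.subject_id for s in bundle.subjects]):
        tr = subject_of_row.isin(train_subjects)
        te = subject_of_row == test_subject
        S_tr, S_te = S.to_numpy()[tr], S.to_numpy()[te]
        mu, sd = S_tr.mean(axis=0), S_tr.std(axis=0)
        sd[sd == 0] = 1.0
        S_tr, S_te = (S_tr - mu) / sd, (S_te - mu) / sd

        if mode == "sf-garg":
            Ghat = reduce_dim(G, d=min(d, len(train_subjects) - 1, G.shape[1]),
                              fit_rows=train_subjects)
            if Ghat.shape[1] < d:  # pad so the elementwise product is defined
                pad = pd.DataFrame(0.0, index=Ghat.index,
                                   columns=[f"pad{k}" for k in range(d - Ghat.shape[1])])
                Ghat = pd.concat([Ghat, pad], axis=1)
            gmu = Ghat.loc[train_subjects].mean(axis=0).to_numpy()
            gsd = Ghat.loc[train_subjects].std(axis=0).to_numpy()
            gsd[gsd == 0] = 1.0
            # Unit-centered scaling: weights start near the multiplicative
            # identity so the fused features begin close to S itself.
            Gz = 1.0 + 0.5 * (Ghat.to_numpy() - gmu) / gsd
            Gz = pd.DataFrame(Gz, index=Ghat.index)
            rows_tr = Gz.loc[subject_of_row[tr]].to_numpy()
            rows_te = Gz.loc[subject_of_row[te]].to_numpy()
            if fusion_style == "weighted":
                X_tr = np.hstack([S_tr, rows_tr])
                X_te = np.hstack([S_te, rows_te])
                clf = FusionMLPClassifier(fusion=True, epochs=mlp_epochs,
                                          lr=mlp_lr, loss=mlp_loss,
                                          class_weight="balanced", seed=seed)
            elif fusion_style == "concat":
                X_tr = np.hstack([S_tr, rows_tr])
                X_te = np.hstack([S_te, rows_te])
                clf = FusionMLPClassifier(fusion=False, epochs=mlp_epochs,
                                          lr=mlp_lr, loss=mlp_loss,
                                          class_weight="balanced", seed=seed)
            else:
                raise ValueError(f"fusion_style must be 'weighted' or 'concat', got {fusion_style!r}")
        else:
            X_tr, X_te = S_tr, S_te
            clf = FusionMLPClassifier(fusion=False, epochs=mlp_epochs,
                                      lr=mlp_lr, loss=mlp_loss,
                                      class_weight="balanced", seed=seed)

        y_tr, y_te = y.to_numpy()[tr], y.to_numpy()[te]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold for subject {test_subject} has one class only")
        clf.fit(X_tr, y_tr)
        y_pred = clf.predict(X_te)
        positive = "high" if task == "arousal" else "positive"
        report.folds.append(FoldResult(
            test_subject=test_subject,
            metrics=compute_metrics(y_te, y_pred, positive_class=positive),
        ))
    return report


def run_pipeline(cfg: PipelineConfig, bundle: DatasetBundle | None = None) -> EvalReport:
    """Run the full pipeline from a data directory (or in-memory bundle).

    Writes the feature matrix, the evaluation report and a manifest (config
    hash + seed) under ``cfg.out_dir``; the run is fully reproducible from
    the manifest.
    """
    if bundle is None:
        bundle = read_bundle(cfg.data_dir)
    report = run_loso(
        bundle, task=cfg.task, mode=cfg.mode, fusion_style=cfg.fusion_style,
        preprocess=cfg.preprocess, embed_dim=cfg.embed_dim,
        embed_epochs=cfg.embed_epochs, embed_negatives=cfg.embed_negatives,
        embed_lambda=cfg.embed_lambda, mlp_epochs=cfg.mlp_epochs,
        mlp_lr=cfg.mlp_lr, mlp_loss=cfg.mlp_loss, seed=cfg.seed,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = preprocess_trials(bundle.recordings, cfg.preprocess, "pafew")
    build_feature_matrix(trials, "pafew").to_csv(out / "features.csv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report


def validate_inputs(data_dir: str | Path, dataset_style: str = "pafew") -> list[str]:
    """Schema/cross-reference validation of an on-disk bundle (report-only).

    Checks CSV headers, the label vocabulary, the sampling-rate sidecar and
    subject cross-references; returns a list of human-readable violations
    (empty for a well-formed bundle).
    """
    src = Path(data_dir)
    violations: list[str] = []

    subj_path, lab_path, sig_path = (src / "subjects.csv", src / "labels.csv",
                                     src / "signals.csv")
    for p in (subj_path, lab_path, sig_path):
        if not p.exists():
            violations.append(f"missing file: {p.name}")
    if not (src / "config.yaml").exists():
        violations.append("missing sampling-rate sidecar config.yaml")
    if violations:
        return violations

    subj = pd.read_csv(subj_path)
    if list(subj.columns) != ["subject_id", "gender", "age"]:
        violations.append(f"subjects.csv header {list(subj.columns)} != "
                          "['subject_id', 'gender', 'age']")
    else:
        bad_gender = subj[~subj.gender.isin(["F", "M"])]
        for r in bad_gender.itertuples():
            violations.append(f"subjects.csv row {r.Index}: invalid gender {r.gender!r}")

    lab = pd.read_csv(lab_path)
    known = set(subj.subject_id.astype(str)) if "subject_id" in subj else set()
    if "emotion" in lab.columns:
        for r in lab.itertuples():
            if r.emotion not in EMOTIONS:
                violations.append(
                    f"labels.csv row {r.Index}: unknown emotion token {r.emotion!r}"
                )
    elif {"valence", "arousal"} <= set(lab.columns):
        bad_v = lab[~lab.valence.isin(["positive", "negative"])]
        bad_a = lab[~lab.arousal.isin(["high", "low"])]
        for r in bad_v.itertuples():
            violations.append(f"labels.csv row {r.Index}: invalid valence {r.valence!r}")
        for r in bad_a.itertuples():
            violations.append(f"labels.csv row {r.Index}: invalid arousal {r.arousal!r}")
    else:
        violations.append("labels.csv lacks both an 'emotion' column and "
                          "'valence'/'arousal' columns")
    for r in lab.itertuples():
        if str(r.subject_id) not in known:
            violations.append(
                f"labels.csv row {r.Index}: unknown subject {r.subject_id!r}"
            )

    sig_cols = list(pd.read_csv(sig_path, nrows=0).columns)
    expected = ["subject_id", "trial_id", "sample_index", "eda_us"]
    if sig_cols != expected:
        violations.append(f"signals.csv header {sig_cols} != {expected}")
    else:
        sig_ids = set(pd.read_csv(sig_path, usecols=["subject_id"]).subject_id.astype(str))
        for sid in sorted(sig_ids - known):
            violations.append(f"signals.csv references unknown subject {sid!r}")
    return violations
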