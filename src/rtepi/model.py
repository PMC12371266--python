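"""Random-forest EPI classifier with the evaluation protocols used throughout.

Provides in-house ranking metrics (AUPRC by average-precision summation with
tied scores collapsed to one threshold; AUROC as the Mann-Whitney rank
statistic), stratified 5-fold cross-validation, repeated stratified
resampling, train-on-row/test-on-column cross-sample matrices, and pooled
("general") models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from rtepi.rt_features import FeatureMatrix, FeatureScheme

#: Default random-forest settings: 500 trees, sqrt features per split,
#: unlimited depth, no class weighting. All overridable per call.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
    "class_weight": None,
    "n_jobs": 1,
}


class DegenerateLabelsError(ValueError):
    """Raised when a metric or fit receives a single-class label vector."""


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    labels = labels.astype(np.int64)
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise DegenerateLabelsError("need at least one positive and one negative")
    return scores, labels


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision summation).

    Scores are processed in descending order; equal scores form a single
    threshold. AP = sum over thresholds of (recall increment) * precision.
    """
    scores, labels = _check_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group boundaries where the sorted score changes
    boundary = np.flatnonzero(np.diff(s) != 0)
    group_ends = np.concatenate([boundary, [len(s) - 1]])
    tp = np.cumsum(y)[group_ends].astype(np.float64)
    n_seen = (group_ends + 1).astype(np.float64)
    precision = tp / n_seen
    n_pos = float(labels.sum())
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def auroc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    scores, labels = _check_scores_labels(scores, labels)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores), dtype=np.float64)
    s = scores[order]
    # midranks for ties
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalResult:
    """Pooled + per-replicate ranking performance of one evaluation run."""

    auprc: float
    auroc: float
    baseline: float
    per_replicate_auprc: list[float] = field(default_factory=list)
    per_replicate_auroc: list[float] = field(default_factory=list)

    @property
    def auprc_mean(self) -> float:
        return float(np.mean(self.per_replicate_auprc))

    @property
    def auprc_sd(self) -> float:
        return float(np.std(self.per_replicate_auprc))

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.per_replicate_auroc))

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.per_replicate_auroc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": range(len(self.per_replicate_auprc)),
                "auprc": self.per_replicate_auprc,
                "auroc": self.per_replicate_auroc,
            }
        )


@dataclass
class TrainedModel:
    """A fitted classifier tied to the feature-column fingerprint it was trained on."""

    classifier: RandomForestClassifier
    feature_names: list[str]
    fingerprint: str
    provenance: list[str]
    seed: int
    hyperparams: dict

    def _check_columns(self, columns: Sequence[str]) -> None:
        if list(columns) != self.feature_names:
            raise ValueError(
                "feature columns do not match the model's scheme fingerprint "
                f"({self.fingerprint})"
            )

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-class probability per row; columns must match training."""
        self._check_columns(features.columns)
        proba = self.classifier.predict_proba(features.to_numpy(dtype=np.float64))
        return proba[:, list(self.classifier.classes_).index(1)]

    def predict_matrix(self, matrix: FeatureMatrix) -> np.ndarray:
        return self.predict_proba(matrix.features)

    def run_log(self) -> dict:
        return {
            "fingerprint": self.fingerprint,
            "provenance": self.provenance,
            "seed": self.seed,
            "hyperparams": {
                k: v for k, v in self.hyperparams.items() if k != "n_jobs"
            },
            "n_features": len(self.feature_names),
        }

    def save(self, path) -> None:
        joblib.dump(
            {"format_version": 1, "model": self, "run_log": self.run_log()}, path
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported model file version in {path}")
        return payload["model"]


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    hyperparams: dict | None,
) -> tuple[RandomForestClassifier, dict]:
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    clf = RandomForestClassifier(random_state=seed, **params)
    clf.fit(X, y)
    return clf, params


def train(
    matrix: FeatureMatrix,
    seed: int = 0,
    hyperparams: dict | None = None,
    columns: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the classifier on a labelled feature matrix (deterministic per seed)."""
    y = matrix.labels
    if y.min() == y.max():
        raise DegenerateLabelsError("training data has a single class")
    feats = matrix.features if columns is None else matrix.subset_columns(columns)
    clf, params = _fit(feats.to_numpy(dtype=np.float64), y, seed, hyperparams)
    sources = sorted(set(matrix.meta.get("source", pd.Series(dtype=str)).astype(str)))
    if columns is None:
        fingerprint = matrix.scheme.fingerprint
    else:
        import hashlib

        fingerprint = hashlib.sha256(
            ";".join(feats.columns).encode()
        ).hexdigest()[:16]
    return TrainedModel(
        classifier=clf,
        feature_names=list(feats.columns),
        fingerprint=fingerprint,
        provenance=[s for s in sources if s],
        seed=seed,
        hyperparams=params,
    )


def _evaluate_scores(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    return auprc(scores, y), auroc(scores, y)


def cross_validate(
    matrix: FeatureMatrix,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    columns: Sequence[str] | None = None,
) -> EvalResult:
    """Stratified k-fold CV; out-of-fold scores pooled for the headline metrics."""
    y = matrix.labels
    feats = matrix.features if columns is None else matrix.subset_columns(columns)
    X = feats.to_numpy(dtype=np.float64)
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise DegenerateLabelsError(
            f"need >= {k} samples of each class for {k}-fold CV; "
            "use a larger dataset"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=np.float64)
    fold_auprc: list[float] = []
    fold_auroc: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf, _ = _fit(X[tr], y[tr], seed + fold, hyperparams)
        proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        oof[te] = proba
        a_pr, a_roc = _evaluate_scores(proba, y[te])
        fold_auprc.append(a_pr)
        fold_auroc.append(a_roc)
    pooled_pr, pooled_roc = _evaluate_scores(oof, y)
    return EvalResult(
        auprc=pooled_pr,
        auroc=pooled_roc,
        baseline=float(y.mean()),
        per_replicate_auprc=fold_auprc,
        per_replicate_auroc=fold_auroc,
    )


def resample_evaluate(
    matrix: FeatureMatrix,
    n_reps: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvalResult:
    """Repeated stratified train/test resampling; reports mean +/- sd."""
    y = matrix.labels
    X = matrix.X
    sss = StratifiedShuffleSplit(
        n_splits=n_reps, test_size=test_fraction, random_state=seed
    )
    rep_auprc: list[float] = []
    rep_auroc: list[float] = []
    for rep, (tr, te) in enumerate(sss.split(X, y)):
        clf, _ = _fit(X[tr], y[tr], seed + rep, hyperparams)
        proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        a_pr, a_roc = _evaluate_scores(proba, y[te])
        rep_auprc.append(a_pr)
        rep_auroc.append(a_roc)
    return EvalResult(
        auprc=float(np.mean(rep_auprc)),
        auroc=float(np.mean(rep_auroc)),
        baseline=float(y.mean()),
        per_replicate_auprc=rep_auprc,
        per_replicate_auroc=rep_auroc,
    )


def evaluate_model(model: TrainedModel, matrix: FeatureMatrix) -> EvalResult:
    """Apply a trained model to an independent labelled matrix."""
    scores = model.predict_proba(matrix.features[model.feature_names])
    y = matrix.labels
    a_pr, a_roc = _evaluate_scores(scores, y)
    return EvalResult(a_pr, a_roc, float(y.mean()), [a_pr], [a_roc])


def cross_sample_matrix(
    datasets: dict[str, FeatureMatrix],
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """AUPRC matrix: train on the row dataset, test on the column dataset.

    Diagonal entries are k-fold cross-validated; off-diagonal entries train on
    the full row dataset and score the full column dataset.
    """
    names = list(datasets)
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for row in names:
        model = train(datasets[row], seed=seed, hyperparams=hyperparams)
        for col in names:
            if row == col:
                out.loc[row, col] = cross_validate(
                    datasets[row], k=k, seed=seed, hyperparams=hyperparams
                ).auprc
            else:
                out.loc[row, col] = evaluate_model(model, datasets[col]).auprc
    return out


def pool_datasets(datasets: dict[str, FeatureMatrix]) -> FeatureMatrix:
    """Row-concatenate datasets sharing one scheme; provenance is retagged."""
    schemes = {m.scheme.fingerprint for m in datasets.values()}
    if len(schemes) != 1:
        raise ValueError("cannot pool datasets with mismatched feature schemes")
    feats = pd.concat(
        [m.features for m in datasets.values()], ignore_index=True
    )
    metas = []
    for name, m in datasets.items():
        meta = m.meta.copy()
        meta["source"] = name
        metas.append(meta)
    meta = pd.concat(metas, ignore_index=True)
    any_scheme = next(iter(datasets.values())).scheme
    return FeatureMatrix(feats, meta, any_scheme)


def train_general(
    datasets: dict[str, FeatureMatrix],
    seed: int = 0,
    hyperparams: dict | None = None,
) -> TrainedModel:
    """Train one pooled model across datasets (schemes must match)."""
    return train(pool_datasets(datasets), seed=seed, hyperparams=hyperparams)


def write_eval_report(path, result: EvalResult, extra: dict | None = None) -> None:
    payload = {
        "auprc": result.auprc,
        "auroc": result.auroc,
        "baseline": result.baseline,
        "auprc_mean": result.auprc_mean,
        "auprc_sd": result.auprc_sd,
        "auroc_mean": result.auroc_mean,
        "auroc_sd": result.auroc_sd,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
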