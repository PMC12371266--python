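"""Feature-importance analysis and controlled evaluations.

Importance is mean impurity decrease by default (a permutation mode exists
because impurity importance is biased toward high-cardinality features);
incremental selection sweeps top-k feature subsets; subset evaluation
restricts cross-validation to a named feature group; the distance-only
control trains on genomic distance alone to verify distance matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from rtepi.model import EvalResult, TrainedModel, cross_validate
from rtepi.rt_features import FeatureMatrix, FeatureScheme, feature_groups, parse_feature_name


def importance(
    model: TrainedModel,
    mode: str = "impurity",
    matrix: FeatureMatrix | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked feature importances with anchor/scale group annotations.

    ``mode='impurity'`` uses the forest's mean impurity decrease (sums to 1);
    ``mode='permutation'`` requires ``matrix`` and scores mean AUC drop under
    column permutation.
    """
    names = model.feature_names
    if mode == "impurity":
        scores = model.classifier.feature_importances_
    elif mode == "permutation":
        if matrix is None:
            raise ValueError("permutation importance requires a feature matrix")
        result = permutation_importance(
            model.classifier,
            matrix.subset_columns(names).to_numpy(dtype=np.float64),
            matrix.labels,
            n_repeats=n_repeats,
            random_state=seed,
            scoring="roc_auc",
        )
        scores = result.importances_mean
    else:
        raise ValueError(f"unknown importance mode {mode!r}")
    anchors, scales = [], []
    for name in names:
        anchor, scale, _, _ = parse_feature_name(name)
        anchors.append(anchor)
        scales.append(f"scale_{scale}")
    table = pd.DataFrame(
        {"feature": names, "importance": scores, "anchor": anchors, "scale": scales}
    )
    return table.sort_values(
        "importance", ascending=False, kind="stable"
    ).reset_index(drop=True)


def group_importance(table: pd.DataFrame, by: str = "anchor") -> pd.Series:
    """Summed importance per group; anchor groups partition the total exactly."""
    if by not in ("anchor", "scale"):
        raise ValueError("by must be 'anchor' or 'scale'")
    return table.groupby(by)["importance"].sum().sort_values(ascending=False)


def incremental_selection(
    matrix: FeatureMatrix,
    ranking: pd.DataFrame,
    k_grid: list[int] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Cross-validated performance of top-k ranked feature subsets.

    Returns a table of (k, auprc, auroc) plus a ``best`` flag at the argmax-k
    by AUPRC. ``k_grid`` must be sorted ascending.
    """
    d = len(ranking)
    if k_grid is None:
        k_grid = [k for k in (5, 10, 20, 30, 50, 100, 200, d) if k <= d]
    if list(k_grid) != sorted(k_grid):
        raise ValueError("k_grid must be sorted ascending")
    if k_grid[-1] > d or k_grid[0] < 1:
        raise ValueError("k_grid entries must lie in [1, number of ranked features]")
    rows = []
    for k in k_grid:
        cols = ranking["feature"].head(k).tolist()
        res = cross_validate(
            matrix, k=k_folds, seed=seed, hyperparams=hyperparams, columns=cols
        )
        rows.append({"k": k, "auprc": res.auprc, "auroc": res.auroc})
    table = pd.DataFrame(rows)
    table["best"] = table["auprc"] == table["auprc"].max()
    return table


def subset_eval(
    matrix: FeatureMatrix,
    group: str,
    k_folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvalResult:
    """Cross-validation restricted to one feature group (see feature_groups)."""
    groups = feature_groups(matrix.scheme)
    if group not in groups:
        raise KeyError(
            f"unknown feature group {group!r}; available: {sorted(groups)}"
        )
    return cross_validate(
        matrix, k=k_folds, seed=seed, hyperparams=hyperparams, columns=groups[group]
    )


def distance_only_control(
    matrix: FeatureMatrix,
    k_folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvalResult:
    """Train on the single distance column; a matched dataset sits at baseline."""
    if "distance" not in matrix.meta.columns:
        raise ValueError("feature matrix lacks a distance metadata column")
    control_scheme = _DistanceScheme()
    control = FeatureMatrix.__new__(FeatureMatrix)
    control.features = matrix.meta[["distance"]].astype(float)
    control.features.columns = ["distance"]
    control.meta = matrix.meta
    control.scheme = control_scheme
    return cross_validate(control, k=k_folds, seed=seed, hyperparams=hyperparams)


class _DistanceScheme:
    """Minimal scheme stand-in for the single-column distance control."""

    feature_names = ["distance"]
    n_features = 1
    fingerprint = "distance-only"
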