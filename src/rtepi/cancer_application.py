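"""Disease-cohort pipeline: per-sample scoring, group-specific interaction calls,
and clustering quality metrics.

Given a trained classifier and per-sample RT profiles from two groups, the
pipeline selects the strongest candidate interactions, re-encodes them with
each sample's RT profile to obtain a samples x interactions probability
matrix, calls interactions present in one group but not the other, and
quantifies how well hierarchical clustering of samples on the called
interactions recovers the group structure (adjusted Rand index,
Calinski-Harabasz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from rtepi.dataset_construction import EPIPair
from rtepi.io_formats import RTProfile
from rtepi.model import TrainedModel
from rtepi.rt_features import FeatureScheme, encode_dataset


def pair_id(pair: EPIPair) -> str:
    e, p = pair.enhancer, pair.promoter
    return f"{pair.chrom}:{e.start}-{e.end}|{p.start}-{p.end}"


@dataclass
class SampleProbabilityMatrix:
    """Samples x interactions matrix of model probabilities with group labels."""

    values: pd.DataFrame  # index = sample_id, columns = pair ids
    groups: pd.Series  # index = sample_id
    pairs: list[EPIPair]

    def __post_init__(self):
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("probability matrix contains missing entries")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if list(self.groups.index) != list(self.values.index):
            raise ValueError("group labels must align with sample rows")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def write(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="sample")


def select_top_epis(
    scored: Sequence[tuple[EPIPair, float]], n: int = 1000
) -> list[tuple[EPIPair, float]]:
    """Top-n candidates by probability.

    Ties at the cutoff break deterministically by (score desc, chrom,
    enhancer start, promoter start).
    """
    ranked = sorted(
        scored,
        key=lambda item: (
            -item[1],
            item[0].chrom,
            item[0].enhancer.start,
            item[0].promoter.start,
        ),
    )
    return ranked[:n]


def build_sample_matrix(
    epis: Sequence[EPIPair],
    model: TrainedModel,
    profiles: Sequence[RTProfile],
    scheme: FeatureScheme | None = None,
) -> SampleProbabilityMatrix:
    """Entry (s, e) = model probability of pair e encoded with sample s's profile."""
    scheme = scheme or FeatureScheme()
    if not epis:
        raise ValueError("no interactions supplied")
    if not profiles:
        raise ValueError("no sample profiles supplied")
    rows = {}
    groups = {}
    for profile in profiles:
        matrix = encode_dataset(list(epis), profile, scheme)
        rows[profile.sample_id] = model.predict_proba(
            matrix.features[model.feature_names]
        )
        groups[profile.sample_id] = profile.group or ""
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=[pair_id(p) for p in epis]
    )
    return SampleProbabilityMatrix(
        values=values,
        groups=pd.Series(groups).loc[values.index],
        pairs=list(epis),
    )


@dataclass
class GroupSpecificCalls:
    """Disjoint partition of the scored interactions by group-level positivity."""

    group_a: str
    group_b: str
    a_specific: list[str]
    common: list[str]
    b_specific: list[str]
    neither: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for call, ids in (
            (f"{self.group_a}_specific", self.a_specific),
            ("common", self.common),
            (f"{self.group_b}_specific", self.b_specific),
            ("neither", self.neither),
        ):
            rows.extend({"epi": i, "call": call} for i in ids)
        return pd.DataFrame(rows)


def call_group_specific(
    matrix: SampleProbabilityMatrix,
    tau_hi: float = 0.5,
    tau_lo: float = 0.5,
    mode: str = "mean",
) -> GroupSpecificCalls:
    """Partition interactions into (A-specific, common, B-specific, neither).

    An interaction is positive in a group when the group's mean probability is
    >= ``tau_hi`` (``mode='mean'``) or when a majority of the group's samples
    individually reach ``tau_hi`` (``mode='majority'``); it is specific to one
    group when positive there and the other group's statistic is < ``tau_lo``.
    """
    group_names = sorted(set(matrix.groups))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")
    ga, gb = group_names
    vals = matrix.values
    if mode == "mean":
        stat_a = vals[matrix.groups == ga].mean(axis=0)
        stat_b = vals[matrix.groups == gb].mean(axis=0)
        pos_a, pos_b = stat_a >= tau_hi, stat_b >= tau_hi
        low_a, low_b = stat_a < tau_lo, stat_b < tau_lo
    elif mode == "majority":
        frac_a = (vals[matrix.groups == ga] >= tau_hi).mean(axis=0)
        frac_b = (vals[matrix.groups == gb] >= tau_hi).mean(axis=0)
        pos_a, pos_b = frac_a > 0.5, frac_b > 0.5
        low_a, low_b = ~pos_a, ~pos_b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cols = vals.columns
    # common takes precedence so the four sets always partition the input
    common = list(cols[pos_a & pos_b])
    a_specific = list(cols[pos_a & ~pos_b & low_b])
    b_specific = list(cols[pos_b & ~pos_a & low_a])
    taken = set(a_specific) | set(b_specific) | set(common)
    neither = [c for c in cols if c not in taken]
    return GroupSpecificCalls(ga, gb, a_specific, common, b_specific, neither)


def hierarchical_cluster(
    matrix: SampleProbabilityMatrix | pd.DataFrame | np.ndarray,
    k: int = 2,
    columns: Sequence[str] | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative clustering of sample rows cut at k clusters (deterministic)."""
    if isinstance(matrix, SampleProbabilityMatrix):
        data = matrix.values
    else:
        data = pd.DataFrame(matrix)
    if columns is not None:
        data = data[list(columns)]
    X = data.to_numpy(dtype=np.float64)
    if not 1 <= k <= len(X):
        raise ValueError("k must lie in [1, number of samples]")
    if k == len(X):
        return np.arange(1, k + 1)
    Z = linkage(X, method=method, metric=metric)
    return fcluster(Z, t=k, criterion="maxclust")


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Permutation-model adjusted Rand index from the contingency table."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D sequences")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial and identical
    return float((sum_ij - expected) / (max_index - expected))


def calinski_harabasz(X, labels) -> float:
    """Between/within dispersion ratio normalised by degrees of freedom.

    Dispersions are traces of the between- and within-cluster scatter
    matrices. Zero within-cluster variance with distinct centroids is a
    degenerate configuration reported as +inf.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = len(X)
    clusters = np.unique(labels)
    k = len(clusters)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n clusters")
    overall = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in clusters:
        members = X[labels == c]
        centroid = members.mean(axis=0)
        between += len(members) * float(np.sum((centroid - overall) ** 2))
        within += float(np.sum((members - centroid) ** 2))
    if within == 0.0:
        return float("inf")
    return float((between / (k - 1)) / (within / (n - k)))


def cluster_quality(
    matrix: SampleProbabilityMatrix,
    columns: Sequence[str],
    k: int = 2,
) -> dict:
    """Cluster samples on the given interaction columns and score vs groups."""
    labels = hierarchical_cluster(matrix, k=k, columns=columns)
    truth = matrix.groups.to_numpy()
    X = matrix.values[list(columns)].to_numpy(dtype=np.float64)
    return {
        "labels": labels,
        "ari": adjusted_rand_index(labels, truth),
        "calinski_harabasz": calinski_harabasz(X, labels),
    }
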