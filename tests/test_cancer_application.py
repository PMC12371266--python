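import itertools

import numpy as np
import pandas as pd
import pytest

from rtepi.cancer_application import (
    GroupSpecificCalls,
    SampleProbabilityMatrix,
    adjusted_rand_index,
    build_sample_matrix,
    calinski_harabasz,
    call_group_specific,
    cluster_quality,
    hierarchical_cluster,
    pair_id,
    select_top_epis,
)
from rtepi.dataset_construction import EPIPair
from rtepi.io_formats import GenomicInterval, RTProfile
from tests.conftest import TINY_SCHEME, constant_profile

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_ari(a, b):
    """ARI by exhaustive pair counting over all C(n,2) index pairs."""
    a, b = list(a), list(b)
    n = len(a)
    n00 = n01 = n10 = n11 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def oracle_ch(X, labels):
    """Direct-formula Calinski-Harabasz."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    clusters = np.unique(labels)
    k = len(clusters)
    mean = X.mean(axis=0)
    b = sum(
        (labels == c).sum() * np.sum((X[labels == c].mean(axis=0) - mean) ** 2)
        for c in clusters
    )
    w = sum(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2) for c in clusters)
    return (b / (k - 1)) / (w / (n - k))


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def make_pairs(n):
    return [
        EPIPair(iv(i * 100_000 + 10_000, i * 100_000 + 11_000),
                iv(i * 100_000 + 50_000, i * 100_000 + 51_000))
        for i in range(n)
    ]


def make_matrix(values, groups):
    """SampleProbabilityMatrix from a 2-D array and group labels."""
    values = np.asarray(values, dtype=float)
    n_samples, n_epis = values.shape
    pairs = make_pairs(n_epis)
    ids = [pair_id(p) for p in pairs]
    samples = [f"s{i}" for i in range(n_samples)]
    frame = pd.DataFrame(values, index=samples, columns=ids)
    return SampleProbabilityMatrix(frame, pd.Series(groups, index=samples), pairs)


class TestSelectTop:
    def test_n_larger_than_candidates_returns_all(self):
        pairs = make_pairs(5)
        scored = list(zip(pairs, [0.1, 0.5, 0.3, 0.9, 0.2]))
        assert len(select_top_epis(scored, n=1000)) == 5

    def test_exactly_n_selected(self):
        pairs = make_pairs(1200)
        rng = np.random.default_rng(0)
        scored = list(zip(pairs, rng.random(1200)))
        assert len(select_top_epis(scored, n=1000)) == 1000

    def test_tie_break_lexicographic(self):
        a = EPIPair(iv(10_000, 11_000), iv(50_000, 51_000))
        b = EPIPair(iv(5_000, 6_000), iv(60_000, 61_000))
        top = select_top_epis([(a, 0.5), (b, 0.5)], n=1)
        assert top[0][0] is b  # smaller enhancer start wins the tie

    def test_sorted_by_score(self):
        pairs = make_pairs(4)
        scored = list(zip(pairs, [0.2, 0.9, 0.4, 0.6]))
        top = select_top_epis(scored, n=4)
        assert [s for _, s in top] == [0.9, 0.6, 0.4, 0.2]


class TestBuildSampleMatrix:
    class ConstModel:
        feature_names = TINY_SCHEME.feature_names
        fingerprint = "stub"

        def predict_proba(self, features):
            return np.full(len(features), 0.7)

    def test_shape(self):
        profiles = [
            constant_profile(1.0, 10_000_000, chrom="chr1") for _ in range(10)
        ]
        for i, p in enumerate(profiles):
            p.sample_id = f"s{i}"
            p.group = "A" if i < 5 else "B"
        mat = build_sample_matrix(make_pairs(50), self.ConstModel(), profiles, TINY_SCHEME)
        assert mat.values.shape == (10, 50)

    def test_identical_profiles_identical_rows(self):
        profiles = []
        for i in range(2):
            p = constant_profile(1.5, 10_000_000)
            p.sample_id = f"s{i}"
            p.group = "A"
            profiles.append(p)
        mat = build_sample_matrix(make_pairs(5), self.ConstModel(), profiles, TINY_SCHEME)
        assert (mat.values.iloc[0] == mat.values.iloc[1]).all()

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            build_sample_matrix([], self.ConstModel(), [constant_profile(1.0)], TINY_SCHEME)
        with pytest.raises(ValueError):
            build_sample_matrix(make_pairs(2), self.ConstModel(), [], TINY_SCHEME)


class TestCallGroupSpecific:
    def test_all_ones_everything_common(self):
        mat = make_matrix(np.ones((4, 6)), ["A", "A", "B", "B"])
        calls = call_group_specific(mat)
        assert len(calls.common) == 6
        assert not calls.a_specific and not calls.b_specific and not calls.neither

    def test_all_zeros_everything_neither(self):
        mat = make_matrix(np.zeros((4, 6)), ["A", "A", "B", "B"])
        calls = call_group_specific(mat)
        assert len(calls.neither) == 6

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mat = make_matrix(rng.random((6, 15)), ["A"] * 3 + ["B"] * 3)
            calls = call_group_specific(
                mat, tau_hi=rng.uniform(0.3, 0.7), tau_lo=rng.uniform(0.3, 0.7)
            )
            groups = [calls.a_specific, calls.common, calls.b_specific, calls.neither]
            flat = [c for g in groups for c in g]
            assert sorted(flat) == sorted(mat.values.columns)
            assert len(flat) == len(set(flat))

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        values = rng.random((6, 10))
        mat = make_matrix(values, ["A"] * 3 + ["B"] * 3)
        swapped = make_matrix(values, ["B"] * 3 + ["A"] * 3)
        calls = call_group_specific(mat)
        calls_swapped = call_group_specific(swapped)
        assert calls.a_specific == calls_swapped.b_specific
        assert calls.b_specific == calls_swapped.a_specific
        assert calls.common == calls_swapped.common

    def test_majority_mode(self):
        values = np.array([[0.9, 0.1], [0.9, 0.1], [0.1, 0.1], [0.2, 0.1]])
        mat = make_matrix(values, ["A", "A", "B", "B"])
        calls = call_group_specific(mat, mode="majority")
        assert calls.a_specific == [mat.values.columns[0]]

    def test_more_than_two_groups_error(self):
        mat = make_matrix(np.ones((3, 2)), ["A", "B", "C"])
        with pytest.raises(ValueError):
            call_group_specific(mat)


class TestHierarchicalCluster:
    def test_separated_blocks_recovered(self):
        values = np.vstack([np.zeros((3, 8)), np.ones((3, 8))])
        labels = hierarchical_cluster(values, k=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_singletons(self):
        values = np.random.default_rng(0).random((5, 4))
        labels = hierarchical_cluster(values, k=5)
        assert len(set(labels)) == 5

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(1)
        row = rng.random(6)
        values = np.vstack([row, row, rng.random(6) + 5, rng.random(6) + 5])
        labels = hierarchical_cluster(values, k=2)
        assert labels[0] == labels[1]


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_trivial_partition_scores_zero(self):
        assert adjusted_rand_index([1, 1, 1, 1], [1, 2, 1, 2]) == pytest.approx(
            oracle_ari([1, 1, 1, 1], [1, 2, 1, 2])
        )
        assert adjusted_rand_index([1, 1, 1, 1], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 15)
        b = rng.integers(0, 4, 15)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        remap = {0: "w", 1: "x", 2: "y", 3: "z"}
        assert adjusted_rand_index(a, [remap[x] for x in b]) == pytest.approx(
            adjusted_rand_index(a, b)
        )

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(4, 21)
            a = rng.integers(0, rng.integers(2, 5), n)
            b = rng.integers(0, rng.integers(2, 5), n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                oracle_ari(a, b), abs=1e-12
            )

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestCalinskiHarabasz:
    def test_increases_with_separation(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(10, 3))
        labels = np.array([0] * 5 + [1] * 5)
        previous = 0.0
        for sep in (1.0, 3.0, 9.0):
            X = base + sep * labels[:, None]
            value = calinski_harabasz(X, labels)
            assert value > previous
            previous = value

    def test_zero_within_variance_is_inf(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == float("inf")

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(5, 30)
            k = rng.integers(2, min(n - 1, 5) + 1)
            labels = rng.integers(0, k, n)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, k, n)
            X = rng.normal(size=(n, rng.integers(1, 5)))
            assert calinski_harabasz(X, labels) == pytest.approx(
                oracle_ch(X, labels), abs=1e-9, rel=1e-9
            )

    def test_degenerate_k_errors(self):
        X = np.random.default_rng(6).random((5, 2))
        with pytest.raises(ValueError):
            calinski_harabasz(X, [0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            calinski_harabasz(X, [0, 1, 2, 3, 4])


class TestClusterQuality:
    def test_well_separated_groups_perfect_ari(self):
        values = np.vstack([np.full((3, 6), 0.9), np.full((3, 6), 0.1)])
        values += np.random.default_rng(7).normal(0, 0.01, values.shape)
        values = np.clip(values, 0, 1)
        mat = make_matrix(values, ["A"] * 3 + ["B"] * 3)
        q = cluster_quality(mat, list(mat.values.columns), k=2)
        assert q["ari"] == 1.0
        assert q["calinski_harabasz"] > 10
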