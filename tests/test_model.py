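import numpy as np
import pandas as pd
import pytest

from rtepi.model import (
    DegenerateLabelsError,
    TrainedModel,
    auprc,
    auroc,
    cross_sample_matrix,
    cross_validate,
    evaluate_model,
    pool_datasets,
    resample_evaluate,
    train,
    train_general,
)
from rtepi.rt_features import FeatureScheme
from tests.conftest import FAST_HP, TINY_SCHEME, make_gaussian_matrix

# ---------------------------------------------------------------------------
# Brute-force oracles: independent, slow, threshold-enumerating implementations
# ---------------------------------------------------------------------------


def oracle_auprc(scores, labels):
    """AP by explicit counting at every distinct threshold (O(n^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def oracle_auroc(scores, labels):
    """All positive-negative comparisons: wins + half-ties (O(n^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=50, tie_prob=0.3):
    n = rng.integers(4, n_max + 1)
    labels = np.zeros(n, dtype=int)
    labels[: rng.integers(1, n)] = 1
    rng.shuffle(labels)
    if rng.random() < tie_prob:
        scores = rng.integers(0, 5, n).astype(float)  # heavy ties
    else:
        scores = rng.normal(size=n)
    return scores, labels


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_perfect_ranking_unordered_input(self):
        assert auprc([0.9, 0.4, 0.8], [1, 0, 1]) == 1.0

    def test_hand_derived_five_sixths(self):
        # PR curve: precision 1 at recall 1/2, precision 2/3 at recall 1
        assert auprc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_ties_processed_as_one_threshold(self):
        # one threshold at 0.5 calls everything: AP = prevalence
        assert auprc([0.5, 0.5, 0.5, 0.5], [1, 0, 0, 1]) == pytest.approx(0.5)

    def test_degenerate_labels_error(self):
        with pytest.raises(DegenerateLabelsError):
            auprc([0.1, 0.2], [1, 1])

    def test_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            scores, labels = random_instance(rng)
            assert auprc(scores, labels) == pytest.approx(
                oracle_auprc(scores, labels), abs=1e-12
            )


class TestAUROC:
    def test_perfect(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([0.3, 0.3, 0.3], [1, 0, 1]) == 0.5

    def test_hand_case_one_inversion(self):
        # comparisons: (0.9 vs 0.8) win, (0.7 vs 0.8) loss -> 0.5
        # (verified against the exhaustive pair-counting oracle)
        assert auroc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(
            oracle_auroc([0.9, 0.8, 0.7], [1, 0, 1])
        )
        assert auroc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.5)

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            scores, labels = random_instance(rng)
            assert auroc(scores, labels) == pytest.approx(
                oracle_auroc(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores, labels = random_instance(rng, tie_prob=0.0)
        for transform in (np.exp, lambda s: 3 * s + 7, np.arctan):
            assert auroc(transform(scores), labels) == pytest.approx(
                auroc(scores, labels)
            )

    def test_degenerate_labels_error(self):
        with pytest.raises(DegenerateLabelsError):
            auroc([0.1, 0.2], [0, 0])


class TestNoSkill:
    def test_random_scores_auprc_near_prevalence(self):
        rng = np.random.default_rng(3)
        n, prevalence = 5_000, 0.05
        labels = np.zeros(n, dtype=int)
        labels[: int(n * prevalence)] = 1
        values = []
        for _ in range(200):
            rng.shuffle(labels)
            values.append(auprc(rng.random(n), labels))
        assert np.mean(values) == pytest.approx(prevalence, abs=0.01)


class TestTrain:
    def test_separable_training_auroc_is_one(self):
        mat = make_gaussian_matrix(300, informative=["promoter|anchor|mean"], effect=20.0)
        model = train(mat, seed=0, hyperparams=FAST_HP)
        scores = model.predict_matrix(mat)
        assert auroc(scores, mat.labels) == 1.0

    def test_permuted_labels_near_prevalence(self):
        rng = np.random.default_rng(4)
        mat = make_gaussian_matrix(
            2_000, prevalence=0.2, informative=["promoter|anchor|mean"], seed=4
        )
        permuted = mat.meta.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        mat.meta = permuted
        res = cross_validate(mat, k=5, seed=4, hyperparams=FAST_HP)
        assert res.auprc == pytest.approx(res.baseline, abs=0.05)

    def test_deterministic(self):
        mat = make_gaussian_matrix(300, informative=["promoter|anchor|mean"])
        a = train(mat, seed=7, hyperparams=FAST_HP).predict_matrix(mat)
        b = train(mat, seed=7, hyperparams=FAST_HP).predict_matrix(mat)
        np.testing.assert_array_equal(a, b)

    def test_single_class_error(self):
        mat = make_gaussian_matrix(50, prevalence=0.0)
        with pytest.raises(DegenerateLabelsError):
            train(mat)

    def test_fingerprint_checked_at_predict(self):
        mat = make_gaussian_matrix(100, informative=["promoter|anchor|mean"])
        model = train(mat, seed=0, hyperparams=FAST_HP)
        other = mat.features.rename(columns={mat.features.columns[0]: "bogus"})
        with pytest.raises(ValueError, match="fingerprint"):
            model.predict_proba(other)

    def test_save_load_round_trip(self, tmp_path):
        mat = make_gaussian_matrix(100, informative=["promoter|anchor|mean"])
        model = train(mat, seed=0, hyperparams=FAST_HP)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            model.predict_matrix(mat), loaded.predict_matrix(mat)
        )
        assert loaded.fingerprint == model.fingerprint


class TestCrossValidate:
    def test_every_sample_scored_once(self):
        mat = make_gaussian_matrix(100, prevalence=0.3)
        res = cross_validate(mat, k=5, seed=0, hyperparams=FAST_HP)
        assert len(res.per_replicate_auprc) == 5
        assert 0 <= res.auprc <= 1

    def test_baseline_is_prevalence(self):
        mat = make_gaussian_matrix(200, prevalence=0.25, seed=5)
        res = cross_validate(mat, k=5, seed=0, hyperparams=FAST_HP)
        assert res.baseline == pytest.approx(mat.labels.mean())

    def test_too_few_positives_error(self):
        mat = make_gaussian_matrix(40, prevalence=0.05, seed=6)
        with pytest.raises(DegenerateLabelsError, match="larger"):
            cross_validate(mat, k=10)


class TestResample:
    def test_replicates_recorded_and_reproducible(self):
        mat = make_gaussian_matrix(200, informative=["promoter|anchor|mean"])
        res = resample_evaluate(mat, n_reps=10, seed=0, hyperparams=FAST_HP)
        assert len(res.per_replicate_auprc) == 10
        assert res.auprc_sd >= 0
        res2 = resample_evaluate(mat, n_reps=10, seed=0, hyperparams=FAST_HP)
        assert res.auprc_mean == res2.auprc_mean


class TestCrossSample:
    def test_same_distribution_off_diagonal_near_diagonal(self):
        # independent draws from one generating process
        a = make_gaussian_matrix(400, informative=["promoter|anchor|mean"], seed=8)
        b = make_gaussian_matrix(400, informative=["promoter|anchor|mean"], seed=18)
        table = cross_sample_matrix({"a": a, "b": b}, seed=0, hyperparams=FAST_HP)
        assert table.shape == (2, 2)
        assert table.loc["a", "b"] == pytest.approx(table.loc["a", "a"], abs=0.15)

    def test_independent_couplings_off_diagonal_at_baseline(self):
        # datasets informative through different, non-overlapping columns
        a = make_gaussian_matrix(600, informative=["promoter|anchor|mean"], seed=9)
        b = make_gaussian_matrix(600, informative=["enhancer|500|up|1"], seed=10)
        table = cross_sample_matrix({"a": a, "b": b}, seed=0, hyperparams=FAST_HP)
        baseline = b.labels.mean()
        assert table.loc["a", "a"] > 2 * baseline
        assert table.loc["a", "b"] == pytest.approx(baseline, abs=0.1)


class TestGeneralModel:
    def test_pooling_copies_matches_single(self):
        mat = make_gaussian_matrix(600, informative=["promoter|anchor|mean"], seed=11)
        single = train(mat, seed=0, hyperparams=FAST_HP)
        pooled = train_general({"a": mat, "b": mat, "c": mat}, seed=0, hyperparams=FAST_HP)
        test = make_gaussian_matrix(600, informative=["promoter|anchor|mean"], seed=12)
        assert evaluate_model(pooled, test).auprc == pytest.approx(
            evaluate_model(single, test).auprc, abs=0.03
        )

    def test_pooled_at_least_worst_single_on_mixture(self):
        a = make_gaussian_matrix(500, informative=["promoter|anchor|mean"], seed=13)
        b = make_gaussian_matrix(500, informative=["enhancer|500|up|1"], seed=14)
        pooled = train_general({"a": a, "b": b}, seed=0, hyperparams=FAST_HP)
        mix = pool_datasets(
            {
                "a": make_gaussian_matrix(300, informative=["promoter|anchor|mean"], seed=15),
                "b": make_gaussian_matrix(300, informative=["enhancer|500|up|1"], seed=16),
            }
        )
        worst = min(
            evaluate_model(train(a, seed=0, hyperparams=FAST_HP), mix).auprc,
            evaluate_model(train(b, seed=0, hyperparams=FAST_HP), mix).auprc,
        )
        assert evaluate_model(pooled, mix).auprc >= worst - 0.02

    def test_scheme_mismatch_error(self):
        a = make_gaussian_matrix(100)
        other_scheme = FeatureScheme(window_sizes=(500,), bins_per_side=2)
        b = make_gaussian_matrix(100, scheme=other_scheme)
        with pytest.raises(ValueError, match="scheme"):
            train_general({"a": a, "b": b})

    def test_provenance_lists_sources(self):
        a = make_gaussian_matrix(200, informative=["promoter|anchor|mean"], seed=17)
        model = train_general({"k562": a, "gm12878": a}, seed=0, hyperparams=FAST_HP)
        assert set(model.provenance) == {"k562", "gm12878"}
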