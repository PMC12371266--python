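"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtepi.dataset_construction import DatasetConfig, build_dataset
from rtepi.io_formats import RTProfile
from rtepi.rt_features import FeatureMatrix, FeatureScheme, encode_dataset
from rtepi.synthetic_data import SimConfig, simulate_cell_line

#: Scaled-down generator settings for fast unit tests.
SMALL_SIM = dict(
    chrom_length=20_000_000,
    n_enhancers=2_500,
    n_promoters=2_500,
    n_loops=200,
)

#: Fast forest for tests that only need qualitative behaviour.
FAST_HP = {"n_estimators": 60}

#: Tiny scheme (10 features) for tests that exercise mechanics, not accuracy.
TINY_SCHEME = FeatureScheme(window_sizes=(500, 1000), bins_per_side=2)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cell_line(SimConfig(seed=11, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    pairs, report = build_dataset(
        small_sim.loops,
        small_sim.enhancers,
        small_sim.promoters,
        DatasetConfig(seed=11),
    )
    return pairs, report


@pytest.fixture(scope="session")
def small_matrix(small_sim, small_dataset) -> FeatureMatrix:
    pairs, _ = small_dataset
    return encode_dataset(pairs, small_sim.profile, FeatureScheme())


def constant_profile(value: float, length: int = 100_000, chrom: str = "chr1") -> RTProfile:
    prof = RTProfile(sample_id="const")
    prof.set_chromosome(chrom, [0], [length], [value])
    return prof


def make_gaussian_matrix(
    n: int,
    prevalence: float = 0.25,
    informative: list[str] | None = None,
    effect: float = 2.0,
    seed: int = 0,
    scheme: FeatureScheme = TINY_SCHEME,
) -> FeatureMatrix:
    """Gaussian-feature matrix with optional label-shifted informative columns."""
    rng = np.random.default_rng(seed)
    names = scheme.feature_names
    y = (rng.random(n) < prevalence).astype(int)
    X = rng.normal(size=(n, len(names)))
    for col in informative or []:
        X[:, names.index(col)] += effect * y
    features = pd.DataFrame(X, columns=names)
    meta = pd.DataFrame(
        {
            "chrom": "chr1",
            "enh_start": np.arange(n) * 10_000,
            "enh_end": np.arange(n) * 10_000 + 1_000,
            "prom_start": np.arange(n) * 10_000 + 5_000,
            "prom_end": np.arange(n) * 10_000 + 6_000,
            "distance": rng.uniform(5_000, 2_000_000, n),
            "label": np.where(y == 1, "positive", "negative"),
            "source": "synthetic",
        }
    )
    return FeatureMatrix(features, meta, scheme)
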