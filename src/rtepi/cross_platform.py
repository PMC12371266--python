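"""Scoring of independent loop catalogues and model combination.

A loop catalogue (e.g. from a different chromatin-interaction platform) is
mapped to enhancer-promoter pairs with the same overlap rule used for
positive calling; each mappable loop receives the maximum predicted
probability over its mapped pairs, and the recovery fraction is the share of
mappable loops at or above a probability threshold. Several models combine by
a union rule: a pair is called if any model calls it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rtepi.dataset_construction import EPIPair, call_positive_epis, merge_elements
from rtepi.io_formats import GenomicInterval, Loop, RTProfile
from rtepi.model import TrainedModel
from rtepi.rt_features import FeatureScheme, encode_dataset

DEFAULT_CALL_THRESHOLD = 0.5


@dataclass
class LoopRecovery:
    """Per-loop scores plus the catalogue-level recovery fraction."""

    table: pd.DataFrame  # chrom, anchors, n_pairs, score, called
    recovery: float
    threshold: float
    n_mappable: int
    n_unmappable: int


def _map_loops_to_pairs(
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    merge_gap: int,
) -> list[list[EPIPair]]:
    """Per-loop lists of mapped E-P pairs (empty where unmappable)."""
    from rtepi.dataset_construction import _ElementIndex

    enh_idx = _ElementIndex(merge_elements(enhancers, merge_gap))
    prom_idx = _ElementIndex(merge_elements(promoters, merge_gap))
    mapped: list[list[EPIPair]] = []
    for loop in loops:
        seen: set[tuple] = set()
        pairs: list[EPIPair] = []
        for a, b in ((loop.anchor_a, loop.anchor_b), (loop.anchor_b, loop.anchor_a)):
            for enh in enh_idx.overlapping(a):
                for prom in prom_idx.overlapping(b):
                    if enh.overlaps(prom):
                        continue
                    pair = EPIPair(enh, prom, "unlabeled")
                    if pair.key not in seen:
                        seen.add(pair.key)
                        pairs.append(pair)
        mapped.append(pairs)
    return mapped


def score_reference_loops(
    model: TrainedModel,
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    profile: RTProfile,
    scheme: FeatureScheme | None = None,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    merge_gap: int = 500,
) -> LoopRecovery:
    """Score an independent loop catalogue with a trained model.

    Each loop's score is the max model probability over its mapped pairs;
    recovery = (#mappable loops with score >= threshold) / (#mappable loops).
    """
    scheme = scheme or FeatureScheme()
    mapped = _map_loops_to_pairs(loops, enhancers, promoters, merge_gap)
    flat: list[EPIPair] = [p for pairs in mapped for p in pairs]
    if not flat:
        raise ValueError("no loop could be mapped to an enhancer-promoter pair")
    matrix = encode_dataset(flat, profile, scheme)
    scores = model.predict_proba(matrix.features[model.feature_names])
    rows = []
    offset = 0
    for loop, pairs in zip(loops, mapped):
        if pairs:
            loop_score = float(np.max(scores[offset : offset + len(pairs)]))
            offset += len(pairs)
        else:
            loop_score = np.nan
        rows.append(
            {
                "chrom": loop.chrom,
                "start_a": loop.anchor_a.start,
                "end_a": loop.anchor_a.end,
                "start_b": loop.anchor_b.start,
                "end_b": loop.anchor_b.end,
                "n_pairs": len(pairs),
                "score": loop_score,
                "called": bool(loop_score >= threshold)
                if not np.isnan(loop_score)
                else False,
            }
        )
    table = pd.DataFrame(rows)
    mappable = table["n_pairs"] > 0
    n_mappable = int(mappable.sum())
    recovery = float(table.loc[mappable, "called"].mean())
    return LoopRecovery(
        table=table,
        recovery=recovery,
        threshold=threshold,
        n_mappable=n_mappable,
        n_unmappable=int((~mappable).sum()),
    )


def combine_models(
    models: Sequence[TrainedModel],
    pairs: Sequence[EPIPair],
    profiles: Sequence[RTProfile],
    scheme: FeatureScheme | None = None,
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> pd.DataFrame:
    """Union combination: a pair is positive if ANY model calls it.

    ``profiles`` aligns with ``models`` (each model scores pairs encoded on
    its own RT profile); pass one profile to share it across models. Returns
    per-model score/call columns plus the combined call.
    """
    if not models:
        raise ValueError("need at least one model")
    if len(profiles) == 1:
        profiles = list(profiles) * len(models)
    if len(profiles) != len(models):
        raise ValueError("profiles must align with models (or be a single profile)")
    scheme = scheme or FeatureScheme()
    out = pd.DataFrame(
        {
            "chrom": [p.chrom for p in pairs],
            "enh_start": [p.enhancer.start for p in pairs],
            "enh_end": [p.enhancer.end for p in pairs],
            "prom_start": [p.promoter.start for p in pairs],
            "prom_end": [p.promoter.end for p in pairs],
        }
    )
    combined = np.zeros(len(pairs), dtype=bool)
    for i, (model, profile) in enumerate(zip(models, profiles)):
        matrix = encode_dataset(list(pairs), profile, scheme)
        scores = model.predict_proba(matrix.features[model.feature_names])
        calls = scores >= threshold
        out[f"score_{i}"] = scores
        out[f"call_{i}"] = calls
        combined |= calls
    out["combined_call"] = combined
    return out


def recovery_from_calls(table: pd.DataFrame, column: str = "combined_call") -> float:
    """Fraction of rows called positive in the given call column."""
    return float(table[column].mean())
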