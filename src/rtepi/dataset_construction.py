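"""Labelled enhancer-promoter pair datasets from loops and element annotations.

Pipeline: merge adjacent same-class elements (default gap <= 500 bp), call
positives from loops whose anchors overlap one merged enhancer and one merged
promoter, enumerate candidate pairs, and draw distance-matched negatives at a
configurable negative:positive ratio (default 1:20, positives:negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from rtepi.io_formats import GenomicInterval, Loop

Label = Literal["positive", "negative", "unlabeled"]

DEFAULT_MERGE_GAP = 500
DEFAULT_NEG_POS_RATIO = 20
DEFAULT_MIN_DISTANCE = 5_000
DEFAULT_MAX_DISTANCE = 2_000_000
DEFAULT_N_DISTANCE_BINS = 15


def default_distance_bins(
    min_distance: int = DEFAULT_MIN_DISTANCE,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    n_bins: int = DEFAULT_N_DISTANCE_BINS,
) -> np.ndarray:
    """Log-spaced distance-bin edges (n_bins + 1 edges)."""
    return np.geomspace(min_distance, max_distance, n_bins + 1)


@dataclass(frozen=True)
class EPIPair:
    """A candidate (enhancer, promoter) pair with label and provenance.

    ``distance`` is midpoint-to-midpoint and is always recomputed from the
    coordinates, never trusted from input.
    """

    enhancer: GenomicInterval
    promoter: GenomicInterval
    label: Label = "unlabeled"
    source: str = ""

    def __post_init__(self):
        if self.enhancer.chrom != self.promoter.chrom:
            raise ValueError("enhancer and promoter must share a chromosome")

    @property
    def chrom(self) -> str:
        return self.enhancer.chrom

    @property
    def distance(self) -> float:
        return abs(self.enhancer.midpoint - self.promoter.midpoint)

    @property
    def key(self) -> tuple:
        """Identity used for deduplication and positive/negative exclusion."""
        return (
            self.chrom,
            self.enhancer.start,
            self.enhancer.end,
            self.promoter.start,
            self.promoter.end,
        )

    def relabel(self, label: Label) -> "EPIPair":
        return EPIPair(self.enhancer, self.promoter, label, self.source)


@dataclass
class DatasetConfig:
    merge_gap: int = DEFAULT_MERGE_GAP
    neg_pos_ratio: int = DEFAULT_NEG_POS_RATIO
    min_distance: int = DEFAULT_MIN_DISTANCE
    max_distance: int = DEFAULT_MAX_DISTANCE
    distance_bins: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")
        if not self.min_distance < self.max_distance:
            raise ValueError("min_distance must be < max_distance")
        if self.distance_bins is None:
            self.distance_bins = default_distance_bins(
                self.min_distance, self.max_distance
            )
        self.distance_bins = np.asarray(self.distance_bins, dtype=float)
        if np.any(np.diff(self.distance_bins) <= 0):
            raise ValueError("distance bin edges must be strictly increasing")


def merge_elements(
    intervals: Sequence[GenomicInterval], merge_gap: int = DEFAULT_MERGE_GAP
) -> list[GenomicInterval]:
    """Merge same-class elements whose gap is <= ``merge_gap`` bp.

    The gap between consecutive sorted intervals is ``next.start - prev.end``;
    overlapping intervals (gap <= 0) always merge. Output is sorted and any
    two consecutive output intervals on a chromosome are separated by a gap
    strictly greater than ``merge_gap``.
    """
    if not intervals:
        return []
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= merge_gap
        ):
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


class _ElementIndex:
    """Overlap lookup over sorted, non-overlapping merged elements."""

    def __init__(self, elements: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]]
        self._by_chrom = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for el in elements:
            by_chrom.setdefault(el.chrom, []).append(el)
        for chrom, els in by_chrom.items():
            els.sort()
            starts = np.array([e.start for e in els], dtype=np.int64)
            ends = np.array([e.end for e in els], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: elements overlap; merge them first")
            self._by_chrom[chrom] = (starts, ends, els)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        if region.chrom not in self._by_chrom:
            return []
        starts, ends, els = self._by_chrom[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return els[lo:hi]


def call_positive_epis(
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    source: str = "",
) -> tuple[list[EPIPair], int]:
    """Positive pairs from loops bridging a merged enhancer and a merged promoter.

    Either anchor orientation is accepted; when an anchor overlaps several
    elements the cross-product of pairs is emitted, then deduplicated. The
    overlapped merged element (not the raw anchor) becomes the pair region.

    Returns ``(positives, n_unmatched_loops)``.
    """
    enh_idx = _ElementIndex(enhancers)
    prom_idx = _ElementIndex(promoters)
    seen: set[tuple] = set()
    positives: list[EPIPair] = []
    unmatched = 0
    for loop in loops:
        matched = False
        for a, b in ((loop.anchor_a, loop.anchor_b), (loop.anchor_b, loop.anchor_a)):
            for enh in enh_idx.overlapping(a):
                for prom in prom_idx.overlapping(b):
                    if enh.overlaps(prom):
                        continue
                    pair = EPIPair(enh, prom, "positive", source)
                    if pair.key not in seen:
                        seen.add(pair.key)
                        positives.append(pair)
                    matched = True
        if not matched:
            unmatched += 1
    return positives, unmatched


def enumerate_candidates(
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    min_distance: int = DEFAULT_MIN_DISTANCE,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    source: str = "",
) -> list[EPIPair]:
    """All same-chromosome E-P pairs with min <= midpoint distance <= max.

    Pairs whose elements overlap are excluded regardless of distance.
    """
    proms_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        proms_by_chrom.setdefault(p.chrom, []).append(p)
    for ps in proms_by_chrom.values():
        ps.sort(key=lambda p: p.midpoint)
    candidates: list[EPIPair] = []
    for enh in enhancers:
        ps = proms_by_chrom.get(enh.chrom)
        if not ps:
            continue
        mids = [p.midpoint for p in ps]
        lo = int(np.searchsorted(mids, enh.midpoint - max_distance))
        hi = int(np.searchsorted(mids, enh.midpoint + max_distance, side="right"))
        for prom in ps[lo:hi]:
            d = abs(enh.midpoint - prom.midpoint)
            if d < min_distance or d > max_distance:
                continue
            if enh.overlaps(prom):
                continue
            candidates.append(EPIPair(enh, prom, "unlabeled", source))
    return candidates


class _OverlapIndex:
    """Overlap lookup over possibly-overlapping intervals (sorted by start)."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([i.start for i in ivs], dtype=np.int64)
            max_ends = np.maximum.accumulate([i.end for i in ivs])
            self._by_chrom[chrom] = (starts, np.asarray(max_ends), ivs)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        if region.chrom not in self._by_chrom:
            return []
        starts, max_ends, ivs = self._by_chrom[region.chrom]
        hi = int(np.searchsorted(starts, region.end, side="left"))
        lo = int(np.searchsorted(max_ends[:hi], region.start, side="right"))
        return [iv for iv in ivs[lo:hi] if iv.end > region.start]


def exclude_loop_overlapping(
    candidates: Sequence[EPIPair], loops: Sequence[Loop]
) -> list[EPIPair]:
    """Drop candidates whose two elements overlap the two anchors of one loop.

    The forbidden set is built once from the candidates' own unique elements,
    so the cost is O(#loops * overlap fan-out + #candidates).
    """

    def _key(iv: GenomicInterval) -> tuple:
        return (iv.chrom, iv.start, iv.end)

    enh_idx = _OverlapIndex({c.enhancer for c in candidates})
    prom_idx = _OverlapIndex({c.promoter for c in candidates})
    forbidden: set[tuple] = set()
    for lp in loops:
        for a, b in ((lp.anchor_a, lp.anchor_b), (lp.anchor_b, lp.anchor_a)):
            for enh in enh_idx.overlapping(a):
                for prom in prom_idx.overlapping(b):
                    forbidden.add((_key(enh), _key(prom)))
    return [
        c for c in candidates if (_key(c.enhancer), _key(c.promoter)) not in forbidden
    ]


@dataclass
class SamplingReport:
    """Per-bin bookkeeping of the distance-matched negative draw."""

    bin_edges: np.ndarray
    positives_per_bin: np.ndarray
    negatives_per_bin: np.ndarray
    shortfall_per_bin: np.ndarray

    @property
    def total_shortfall(self) -> int:
        return int(self.shortfall_per_bin.sum())


def _bin_index(distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin membership with the last bin closed on the right; -1 = out of range."""
    idx = np.searchsorted(edges, distances, side="right") - 1
    idx[distances == edges[-1]] = len(edges) - 2
    idx[(distances < edges[0]) | (distances > edges[-1])] = -1
    return idx


def sample_negatives(
    positives: Sequence[EPIPair],
    candidates: Sequence[EPIPair],
    cfg: DatasetConfig,
) -> tuple[list[EPIPair], SamplingReport]:
    """Distance-matched negatives at ``cfg.neg_pos_ratio`` per positive.

    For each distance bin the sampler draws (positives in bin) * ratio
    candidates uniformly without replacement; bins with too few candidates
    contribute everything they have and the deficit is recorded as shortfall.
    Candidates must already exclude every positive pair identity.
    """
    if not positives:
        raise ValueError("no positive pairs supplied")
    if not candidates:
        raise ValueError("no candidate pairs supplied")
    pos_keys = {p.key for p in positives}
    if any(c.key in pos_keys for c in candidates):
        raise ValueError("candidates must exclude positive pair identities")
    edges = cfg.distance_bins
    n_bins = len(edges) - 1
    pos_bins = _bin_index(np.array([p.distance for p in positives]), edges)
    cand_bins = _bin_index(np.array([c.distance for c in candidates]), edges)
    rng = np.random.default_rng(cfg.seed)
    pos_counts = np.zeros(n_bins, dtype=np.int64)
    neg_counts = np.zeros(n_bins, dtype=np.int64)
    shortfall = np.zeros(n_bins, dtype=np.int64)
    negatives: list[EPIPair] = []
    cand_arr = np.array(candidates, dtype=object)
    for b in range(n_bins):
        n_pos = int(np.sum(pos_bins == b))
        pos_counts[b] = n_pos
        if n_pos == 0:
            continue
        want = n_pos * cfg.neg_pos_ratio
        pool = np.flatnonzero(cand_bins == b)
        take = min(want, len(pool))
        shortfall[b] = want - take
        chosen = rng.choice(pool, size=take, replace=False)
        chosen.sort()
        negatives.extend(c.relabel("negative") for c in cand_arr[chosen])
        neg_counts[b] = take
    report = SamplingReport(edges, pos_counts, neg_counts, shortfall)
    return negatives, report


def build_dataset(
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    cfg: DatasetConfig | None = None,
    source: str = "",
) -> tuple[list[EPIPair], SamplingReport]:
    """End-to-end dataset construction; returns labelled pairs and the report.

    Elements are merged, positives called from the loops, candidates
    enumerated and stripped of positive identities and of any pair bridging a
    loop's two anchors, then distance-matched negatives are drawn.
    """
    cfg = cfg or DatasetConfig()
    enh = merge_elements(enhancers, cfg.merge_gap)
    prom = merge_elements(promoters, cfg.merge_gap)
    positives, _ = call_positive_epis(loops, enh, prom, source=source)
    candidates = enumerate_candidates(
        enh, prom, cfg.min_distance, cfg.max_distance, source=source
    )
    pos_keys = {p.key for p in positives}
    candidates = [c for c in candidates if c.key not in pos_keys]
    candidates = exclude_loop_overlapping(candidates, loops)
    in_range = [
        p for p in positives if cfg.min_distance <= p.distance <= cfg.max_distance
    ]
    negatives, report = sample_negatives(in_range, candidates, cfg)
    return in_range + negatives, report


# ---------------------------------------------------------------------------
# Pair table serialization
# ---------------------------------------------------------------------------

PAIR_COLUMNS = [
    "chrom",
    "enh_start",
    "enh_end",
    "prom_start",
    "prom_end",
    "distance",
    "label",
    "source",
]


def pairs_to_frame(pairs: Sequence[EPIPair]) -> pd.DataFrame:
    rows = [
        (
            p.chrom,
            p.enhancer.start,
            p.enhancer.end,
            p.promoter.start,
            p.promoter.end,
            p.distance,
            p.label,
            p.source,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[EPIPair]:
    return [
        EPIPair(
            GenomicInterval(r.chrom, int(r.enh_start), int(r.enh_end)),
            GenomicInterval(r.chrom, int(r.prom_start), int(r.prom_end)),
            r.label,
            "" if pd.isna(r.source) else str(r.source),
        )
        for r in frame.itertuples()
    ]


def write_pairs(path, pairs: Sequence[EPIPair]) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[EPIPair]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return frame_to_pairs(frame)
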