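"""Multi-scale replication-timing feature encoding for enhancer-promoter pairs.

Each pair is described by, per anchor (enhancer and promoter): an optional
anchor-region mean plus, for every window scale, fixed numbers of upstream and
downstream flanking windows summarised by their length-weighted mean RT. With
the default scheme (6 scales x 20 windows per side per scale + anchor means)
this yields 2 x (1 + 6 x 40) = 482 features.

Feature names encode their coordinates as ``{anchor}|{scale}|{side}|{bin}``
(e.g. ``promoter|500|up|3``) or ``{anchor}|anchor|mean``, and parse back via
:func:`parse_feature_name`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from rtepi.dataset_construction import EPIPair
from rtepi.io_formats import DEFAULT_MIN_COVERAGE, RTProfile

DEFAULT_WINDOW_SIZES = (500, 1000, 2000, 5000, 10000, 50000)
DEFAULT_BINS_PER_SIDE = 20

ANCHORS = ("enhancer", "promoter")

Imputation = Literal["chromosome_mean", "zero", "none"]


@dataclass(frozen=True)
class FeatureScheme:
    """Configuration of the multi-scale encoder.

    ``bins_per_side`` windows of each scale tile leftward from the anchor
    start (upstream, bin 1 nearest the anchor) and rightward from the anchor
    end (downstream). Windows truncated by the chromosome origin, or covered
    below ``min_coverage``, become missing and are imputed per ``imputation``.
    """

    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    bins_per_side: int = DEFAULT_BINS_PER_SIDE
    include_anchor_mean: bool = True
    imputation: Imputation = "chromosome_mean"
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __post_init__(self):
        if not self.window_sizes or any(w <= 0 for w in self.window_sizes):
            raise ValueError("window_sizes must be positive")
        if len(set(self.window_sizes)) != len(self.window_sizes):
            raise ValueError("window_sizes must be distinct")
        if self.bins_per_side < 1:
            raise ValueError("bins_per_side must be >= 1")

    @property
    def n_features(self) -> int:
        per_anchor = int(self.include_anchor_mean) + len(self.window_sizes) * (
            2 * self.bins_per_side
        )
        return 2 * per_anchor

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for anchor in ANCHORS:
            if self.include_anchor_mean:
                names.append(f"{anchor}|anchor|mean")
            for w in self.window_sizes:
                for side in ("up", "down"):
                    for b in range(1, self.bins_per_side + 1):
                        names.append(f"{anchor}|{w}|{side}|{b}")
        return names

    @property
    def fingerprint(self) -> str:
        import hashlib

        payload = ";".join(self.feature_names).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_config_text(self) -> str:
        lines = [
            "[feature_scheme]",
            f"window_sizes = {','.join(str(w) for w in self.window_sizes)}",
            f"bins_per_side = {self.bins_per_side}",
            f"include_anchor_mean = {str(self.include_anchor_mean).lower()}",
            f"imputation = {self.imputation}",
            f"min_coverage = {self.min_coverage}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "FeatureScheme":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "[")):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            window_sizes=tuple(int(t) for t in kv["window_sizes"].split(",")),
            bins_per_side=int(kv["bins_per_side"]),
            include_anchor_mean=kv["include_anchor_mean"] == "true",
            imputation=kv["imputation"],  # type: ignore[arg-type]
            min_coverage=float(kv["min_coverage"]),
        )


def parse_feature_name(name: str) -> tuple[str, str, str, int | None]:
    """``(anchor, scale, side, bin)``; anchor-mean features give ('anchor','mean',None)."""
    parts = name.split("|")
    if len(parts) == 3 and parts[1] == "anchor" and parts[2] == "mean":
        return parts[0], "anchor", "mean", None
    if len(parts) == 4:
        return parts[0], parts[1], parts[2], int(parts[3])
    raise ValueError(f"unparseable feature name {name!r}")


def _window_bounds(
    scheme: FeatureScheme, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor window starts/ends, shape (n_pairs, windows_per_anchor).

    Column order matches the per-anchor slice of ``scheme.feature_names``
    (anchor mean first when enabled, then per scale: up bins 1..B, down 1..B).
    Bounds are unclipped here; the encoder clips at the chromosome origin and
    judges coverage against the original window length, so truncated windows
    fall under the missing-data rule.
    """
    cols_s: list[np.ndarray] = []
    cols_e: list[np.ndarray] = []
    if scheme.include_anchor_mean:
        cols_s.append(starts)
        cols_e.append(ends)
    for w in scheme.window_sizes:
        for b in range(1, scheme.bins_per_side + 1):
            cols_s.append(starts - b * w)
            cols_e.append(starts - (b - 1) * w)
        for b in range(1, scheme.bins_per_side + 1):
            cols_s.append(ends + (b - 1) * w)
            cols_e.append(ends + b * w)
    ws = np.stack(cols_s, axis=1)
    we = np.stack(cols_e, axis=1)
    return ws, we


def encode_pairs_array(
    pairs: Sequence[EPIPair], profile: RTProfile, scheme: FeatureScheme
) -> np.ndarray:
    """Feature rows for ``pairs`` (order preserved), shape (n, scheme.n_features)."""
    n = len(pairs)
    out = np.empty((n, scheme.n_features), dtype=np.float64)
    if n == 0:
        return out
    chroms = {p.chrom for p in pairs}
    for chrom in chroms:
        if not profile.has_chromosome(chrom):
            raise KeyError(f"chromosome {chrom!r} absent from RT profile")
    idx = np.arange(n)
    half = scheme.n_features // 2
    for chrom in sorted(chroms):
        rows = np.array([i for i in idx if pairs[i].chrom == chrom])
        chrom_mean = profile.chromosome_mean(chrom)
        for a_i, anchor in enumerate(ANCHORS):
            regions = [
                getattr(pairs[i], anchor) for i in rows
            ]
            starts = np.array([r.start for r in regions], dtype=np.int64)
            ends = np.array([r.end for r in regions], dtype=np.int64)
            ws, we = _window_bounds(scheme, starts, ends)
            orig_len = (we - ws).astype(np.float64)
            ws_c = np.clip(ws, 0, None)
            we_c = np.maximum(we, ws_c)  # fully clipped window -> zero length
            wv, cov = profile.weighted_sums(chrom, ws_c.ravel(), we_c.ravel())
            wv = wv.reshape(ws.shape)
            cov = cov.reshape(ws.shape)
            with np.errstate(invalid="ignore", divide="ignore"):
                flat = wv / cov
            flat[cov / orig_len < scheme.min_coverage] = np.nan
            if scheme.imputation == "chromosome_mean":
                flat = np.where(np.isnan(flat), chrom_mean, flat)
            elif scheme.imputation == "zero":
                flat = np.where(np.isnan(flat), 0.0, flat)
            out[rows, a_i * half : (a_i + 1) * half] = flat
    return out


def encode_pair(
    pair: EPIPair, profile: RTProfile, scheme: FeatureScheme | None = None
) -> np.ndarray:
    """Encode one pair; returns a vector of length ``scheme.n_features``."""
    scheme = scheme or FeatureScheme()
    return encode_pairs_array([pair], profile, scheme)[0]


@dataclass
class FeatureMatrix:
    """Encoded pairs: named feature columns plus label/metadata columns.

    ``features`` holds only encoder output (column count equals the scheme
    dimensionality); ``meta`` carries chrom/coordinates/distance/label/source.
    Distance is metadata, not a default model feature.
    """

    features: pd.DataFrame
    meta: pd.DataFrame
    scheme: FeatureScheme

    def __post_init__(self):
        if list(self.features.columns) != self.scheme.feature_names:
            raise ValueError("feature columns do not match scheme")
        if len(self.features) != len(self.meta):
            raise ValueError("features/meta row mismatch")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: positive=1, anything else=0."""
        return (self.meta["label"] == "positive").to_numpy(dtype=np.int64)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=np.float64)

    def subset_columns(self, columns: Sequence[str]) -> pd.DataFrame:
        missing = [c for c in columns if c not in self.features.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing[:3]}...")
        return self.features[list(columns)]

    def subset_rows(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(
            self.features.iloc[indices].reset_index(drop=True),
            self.meta.iloc[indices].reset_index(drop=True),
            self.scheme,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.features.reset_index(drop=True)],
            axis=1,
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, scheme: FeatureScheme) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        meta_cols = [c for c in frame.columns if "|" not in c]
        mat = cls(frame[scheme.feature_names], frame[meta_cols], scheme)
        return mat


def encode_dataset(
    pairs: Sequence[EPIPair],
    profile: RTProfile,
    scheme: FeatureScheme | None = None,
) -> FeatureMatrix:
    """Encode a pair list into a :class:`FeatureMatrix` (row order preserved)."""
    scheme = scheme or FeatureScheme()
    from rtepi.dataset_construction import pairs_to_frame

    values = encode_pairs_array(pairs, profile, scheme)
    features = pd.DataFrame(values, columns=scheme.feature_names)
    meta = pairs_to_frame(pairs)
    return FeatureMatrix(features, meta, scheme)


def feature_groups(scheme: FeatureScheme) -> dict[str, list[str]]:
    """Column groups by anchor and by scale.

    Every feature belongs to exactly one anchor group (``promoter`` /
    ``enhancer``) and one scale group (``scale_<w>``, or ``scale_anchor`` for
    the anchor-mean features). The key ``all`` maps to every feature.
    """
    groups: dict[str, list[str]] = {"all": list(scheme.feature_names)}
    for name in scheme.feature_names:
        anchor, scale, _, _ = parse_feature_name(name)
        groups.setdefault(anchor, []).append(name)
        groups.setdefault(f"scale_{scale}", []).append(name)
    return groups
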