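"""Genomic interval, loop and replication-timing signal types plus format I/O.

All coordinates are 0-based half-open (BED convention) internally; wiggle's
1-based formats are converted at the parsing boundary. Strand is ignored
throughout.

Supported formats: BED3+ (read/write), BEDPE (read/write), bedGraph and
fixedStep/variableStep wiggle (read), bigWig (read, only when the optional
``pyBigWig`` dependency is present -- see :data:`HAS_BIGWIG`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:  # optional capability, not part of the base install
    import pyBigWig  # type: ignore

    HAS_BIGWIG = True
except ImportError:  # pragma: no cover
    pyBigWig = None
    HAS_BIGWIG = False

#: Sentinel returned by signal queries whose coverage is below threshold.
MISSING = float("nan")

#: Default minimum fraction of a query region that must be covered by the
#: profile for :func:`mean_signal` to return a value instead of the marker.
DEFAULT_MIN_COVERAGE = 0.5


class ParseError(ValueError):
    """Raised when a genomic text format cannot be parsed; carries line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span with 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "requires 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal anchor pair; anchors stored in sorted order."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float | None = None

    def __post_init__(self):
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.score is not None and self.score < 0:
            raise ValueError("loop score must be non-negative")
        if self.anchor_a.start > self.anchor_b.start:
            a, b = self.anchor_b, self.anchor_a
            object.__setattr__(self, "anchor_a", a)
            object.__setattr__(self, "anchor_b", b)

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom


class RTProfile:
    """A queryable per-chromosome replication-timing signal.

    Stores, per chromosome, sorted non-overlapping steps ``[start, end) -> value``
    (early > late by the Repli-seq log-ratio convention). Queries are
    length-weighted means over the intersection with covered bases, with a
    missing-data policy controlled by a coverage-fraction threshold.
    """

    def __init__(
        self,
        steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        sample_id: str = "",
        group: str | None = None,
    ):
        self.sample_id = sample_id
        self.group = group
        # chrom -> (starts, ends, values), plus prefix sums for O(1) queries
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cums: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if steps:
            for chrom, (s, e, v) in steps.items():
                self.set_chromosome(chrom, s, e, v)

    def set_chromosome(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("starts/ends/values length mismatch")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: empty or inverted step")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping steps in RT profile")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{chrom}: non-finite RT value")
        self._steps[chrom] = (starts, ends, values)
        lengths = (ends - starts).astype(np.float64)
        # prefix sums of value*length and of covered length
        cum_wv = np.concatenate(([0.0], np.cumsum(values * lengths)))
        cum_len = np.concatenate(([0.0], np.cumsum(lengths)))
        self._cums[chrom] = (cum_wv, cum_len)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._steps)

    def has_chromosome(self, chrom: str) -> bool:
        return chrom in self._steps

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    def chromosome_bounds(self, chrom: str) -> tuple[int, int]:
        s, e, _ = self._steps[chrom]
        return int(s[0]), int(e[-1])

    def chromosome_mean(self, chrom: str) -> float:
        """Length-weighted mean of the whole chromosome's signal."""
        cum_wv, cum_len = self._cums[chrom]
        return float(cum_wv[-1] / cum_len[-1])

    def weighted_sums(self, chrom: str, starts, ends) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (sum of value*overlap_len, covered_len) for query ranges."""
        if chrom not in self._steps:
            raise KeyError(f"chromosome {chrom!r} absent from profile")
        qs = np.asarray(starts, dtype=np.int64)
        qe = np.asarray(ends, dtype=np.int64)
        ps, pe, pv = self._steps[chrom]
        cum_wv, cum_len = self._cums[chrom]
        # steps fully strictly before the query start / after the query end
        lo = np.searchsorted(pe, qs, side="right")
        hi = np.searchsorted(ps, qe, side="left")
        lo2 = np.maximum(lo, 0)
        wv = cum_wv[hi] - cum_wv[lo2]
        cov = cum_len[hi] - cum_len[lo2]
        # trim the partially-overlapped boundary steps
        has = hi > lo
        idx_lo = np.clip(lo, 0, len(ps) - 1)
        trim_left = np.where(has, np.maximum(qs - ps[idx_lo], 0), 0)
        idx_hi = np.clip(hi - 1, 0, len(ps) - 1)
        trim_right = np.where(has, np.maximum(pe[idx_hi] - qe, 0), 0)
        wv = wv - trim_left * np.where(has, pv[idx_lo], 0.0) - trim_right * np.where(
            has, pv[idx_hi], 0.0
        )
        cov = cov - trim_left - trim_right
        return wv, cov.astype(np.float64)

    def mean_many(
        self,
        chrom: str,
        starts,
        ends,
        min_coverage: float = DEFAULT_MIN_COVERAGE,
    ) -> np.ndarray:
        """Length-weighted means for many ranges; NaN where coverage < threshold."""
        qs = np.asarray(starts, dtype=np.int64)
        qe = np.asarray(ends, dtype=np.int64)
        if np.any(qe <= qs):
            raise ValueError("query ranges must satisfy start < end")
        wv, cov = self.weighted_sums(chrom, qs, qe)
        lengths = (qe - qs).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = wv / cov
        means[cov / lengths < min_coverage] = MISSING
        return means


def mean_signal(
    profile: RTProfile,
    region: GenomicInterval,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> float:
    """Length-weighted mean RT over ``region``; NaN if covered fraction < threshold.

    A region falling entirely outside annotated space (including an unknown
    chromosome) yields the missing marker, never an error.
    """
    if not profile.has_chromosome(region.chrom):
        return MISSING
    return float(
        profile.mean_many(
            region.chrom, [region.start], [region.end], min_coverage=min_coverage
        )[0]
    )


def is_missing(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield line_no, line


def _parse_coord(path, line_no: int, token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(path, line_no, f"non-integer {what}: {token!r}") from None


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file; extra columns ignored, headers/comments skipped."""
    intervals: list[GenomicInterval] = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise ParseError(path, line_no, "expected >= 3 BED columns")
        chrom = fields[0]
        start = _parse_coord(path, line_no, fields[1], "start")
        end = _parse_coord(path, line_no, fields[2], "end")
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from None
    return intervals


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path) -> tuple[list[Loop], int]:
    """Read BEDPE loops.

    Returns ``(loops, n_skipped_interchromosomal)``. Anchor order is
    normalised; inter-chromosomal records are dropped and counted.
    """
    loops: list[Loop] = []
    skipped = 0
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        if len(fields) < 6:
            raise ParseError(path, line_no, "expected >= 6 BEDPE columns")
        c1, c2 = fields[0], fields[3]
        s1 = _parse_coord(path, line_no, fields[1], "start1")
        e1 = _parse_coord(path, line_no, fields[2], "end1")
        s2 = _parse_coord(path, line_no, fields[4], "start2")
        e2 = _parse_coord(path, line_no, fields[5], "end2")
        score = None
        if len(fields) >= 8 and fields[7] not in (".", ""):
            try:
                score = float(fields[7])
            except ValueError:
                raise ParseError(path, line_no, f"bad score {fields[7]!r}") from None
        if c1 != c2:
            skipped += 1
            continue
        try:
            loops.append(
                Loop(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2), score)
            )
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from None
    return loops, skipped


def write_bedpe(path, loops: Sequence[Loop]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            score = "." if lp.score is None else repr(lp.score)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t.\t{score}\n"
            )


# ---------------------------------------------------------------------------
# RT signal tracks: bedGraph / wiggle / bigWig
# ---------------------------------------------------------------------------


def _finish_profile(
    records: dict[str, list[tuple[int, int, float]]],
    sample_id: str,
    group: str | None,
) -> RTProfile:
    profile = RTProfile(sample_id=sample_id, group=group)
    for chrom, recs in records.items():
        starts, ends, values = zip(*recs)
        profile.set_chromosome(chrom, starts, ends, values)
    return profile


def read_bedgraph(path, sample_id: str = "", group: str | None = None) -> RTProfile:
    records: dict[str, list[tuple[int, int, float]]] = {}
    for line_no, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(path, line_no, "expected 4 bedGraph columns")
        chrom = fields[0]
        start = _parse_coord(path, line_no, fields[1], "start")
        end = _parse_coord(path, line_no, fields[2], "end")
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(path, line_no, f"bad value {fields[3]!r}") from None
        if not math.isfinite(value):
            raise ParseError(path, line_no, f"non-finite value {fields[3]!r}")
        if end <= start:
            raise ParseError(path, line_no, f"empty interval [{start},{end})")
        records.setdefault(chrom, []).append((start, end, value))
    try:
        return _finish_profile(records, sample_id or Path(path).stem, group)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def read_wig(path, sample_id: str = "", group: str | None = None) -> RTProfile:
    """Read fixedStep/variableStep wiggle (1-based, converted to 0-based)."""
    records: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # ("fixed", chrom, pos0, step, span) or ("variable", chrom, span)
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                if "chrom" not in kv:
                    raise ParseError(path, line_no, "wig header lacks chrom")
                span = int(kv.get("span", 1))
                if line.startswith("fixedStep"):
                    start0 = int(kv["start"]) - 1  # wig is 1-based
                    step = int(kv.get("step", span))
                    mode = ["fixed", kv["chrom"], start0, step, span]
                else:
                    mode = ["variable", kv["chrom"], span]
                continue
            if mode is None:
                raise ParseError(path, line_no, "wig data before header")
            try:
                if mode[0] == "fixed":
                    value = float(line)
                    _, chrom, pos, step, span = mode
                    records.setdefault(chrom, []).append((pos, pos + span, value))
                    mode[2] = pos + step
                else:
                    pos_s, val_s = line.split()
                    _, chrom, span = mode
                    pos = int(pos_s) - 1
                    value = float(val_s)
                    records.setdefault(chrom, []).append((pos, pos + span, value))
            except ValueError:
                raise ParseError(path, line_no, f"bad wig data line {line!r}") from None
            if not math.isfinite(value):
                raise ParseError(path, line_no, "non-finite value")
    try:
        return _finish_profile(records, sample_id or Path(path).stem, group)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def read_bigwig(path, sample_id: str = "", group: str | None = None) -> RTProfile:
    if not HAS_BIGWIG:  # pragma: no cover
        raise RuntimeError("bigWig support requires the optional pyBigWig dependency")
    bw = pyBigWig.open(str(path))  # pragma: no cover
    try:  # pragma: no cover
        records = {
            chrom: [(s, e, v) for s, e, v in bw.intervals(chrom) if math.isfinite(v)]
            for chrom in bw.chroms()
        }
        return _finish_profile(records, sample_id or Path(path).stem, group)
    finally:  # pragma: no cover
        bw.close()


_RT_READERS = {"bedGraph": read_bedgraph, "wig": read_wig, "bigWig": read_bigwig}

_EXTENSIONS = {
    ".bedgraph": "bedGraph",
    ".bdg": "bedGraph",
    ".wig": "wig",
    ".bw": "bigWig",
    ".bigwig": "bigWig",
}


def read_rt_profile(
    path,
    format: str | None = None,
    sample_id: str = "",
    group: str | None = None,
) -> RTProfile:
    """Read an RT track; format auto-detected from the extension unless given."""
    if format is None:
        format = _EXTENSIONS.get(Path(path).suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer RT track format from {path}")
    if format not in _RT_READERS:
        raise ValueError(f"unknown RT track format {format!r}")
    return _RT_READERS[format](path, sample_id=sample_id, group=group)


def write_bedgraph(path, profile: RTProfile) -> None:
    with open(path, "w") as fh:
        for chrom in profile.chromosomes:
            starts, ends, values = profile.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
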