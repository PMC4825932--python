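"""Interval I/O and binary mark-track handling.

Genomic coordinates are 0-based half-open (the BED convention) everywhere in
memory.  Per-chromosome interval sets are kept as paired, sorted numpy arrays
of starts and ends, merged so that intervals never overlap or touch; score
tracks are run-length encoded.  All overlay/threshold/mean operations are
exact and are cross-checked against per-basepair oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

#: Canonical mark order: seven histone modifications plus DNase I
#: hypersensitivity, the eight-track binarized epigenome used throughout.
DEFAULT_MARKS: tuple[str, ...] = (
    "H3K4me1",
    "H3K4me3",
    "H3K36me3",
    "H3K27me3",
    "H3K9me3",
    "H3K27ac",
    "H3K9ac",
    "DNase",
)

N_MARKS = 8
N_PATTERNS = 1 << N_MARKS  # 256 distinct 8-bit mark patterns

#: (256, 8) matrix whose row k is the binary mark vector with pattern code k
#: (bit i of k = mark i present).
PATTERNS: np.ndarray = (
    (np.arange(N_PATTERNS)[:, None] >> np.arange(N_MARKS)) & 1
).astype(np.float64)


class PeakParseError(ValueError):
    """Raised when a peak/BED file line cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised when a track-set configuration is incomplete or inconsistent."""


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return 3

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# low-level interval arithmetic on (starts, ends) array pairs
# ---------------------------------------------------------------------------

def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping or book-ended intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # an interval starts a new merged block iff its start exceeds the running
    # maximum end of everything before it (book-ended intervals merge)
    run_max_end = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_max_end[:-1]
    block_idx = np.cumsum(new_block) - 1
    out_starts = starts[new_block]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    del block_idx
    return out_starts, out_ends


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/book-ended intervals; result sorted by (chrom, start)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.start >= iv.end:
            raise ValueError(f"degenerate interval {iv}")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        arr = np.asarray(by_chrom[chrom], dtype=np.int64)
        s, e = _merge_arrays(arr[:, 0], arr[:, 1])
        out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(s, e))
    return out


def _coverage_at(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean coverage of sorted, merged intervals at each queried position."""
    pos = np.asarray(pos, dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    cov = idx >= 0
    if cov.any():
        cov_idx = idx[cov]
        cov[cov] = pos[cov] < ends[cov_idx]
    return cov


def _segment_bounds(interval_sets: Sequence[tuple[np.ndarray, np.ndarray]],
                    length: int) -> np.ndarray:
    """Sorted unique breakpoints partitioning [0, length) so that every input
    interval set is constant within each segment."""
    pieces = [np.array([0, length], dtype=np.int64)]
    for s, e in interval_sets:
        pieces.append(s)
        pieces.append(e)
    bounds = np.unique(np.concatenate(pieces))
    return bounds[(bounds >= 0) & (bounds <= length)]


# ---------------------------------------------------------------------------
# peak-file parsing
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_peak_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval]:
    """Read peak calls from a BED3+ or ENCODE narrowPeak file.

    Only the first three columns (chrom, start, end) are used; additional
    columns (narrowPeak has ten) are ignored.  Returned intervals are sorted
    by (chrom, start) and merged where overlapping or book-ended.
    """
    if format not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    raw: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise PeakParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start < 0 or start >= end:
                raise PeakParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            raw.append(GenomicInterval(chrom, start, end))
    return merge_intervals(raw)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genome_file(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` genome-size file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PeakParseError(f"{path}:{lineno}: expected chrom and length")
            genome[fields[0]] = int(fields[1])
    return genome


def write_genome_file(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# MarkTrackSet
# ---------------------------------------------------------------------------

@dataclass
class MarkTrackSet:
    """Binary coverage of the eight epigenetic marks over a genome.

    ``coverage[mark][chrom]`` is a ``(starts, ends)`` pair of sorted, merged
    int64 arrays; a basepair is "1" for that mark iff it lies in one of the
    intervals.  The mark order is fixed at construction and is inherited by
    every mark vector and parameter vector derived from the set.
    """

    tissue_label: str
    marks: tuple[str, ...]
    coverage: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        self.marks = tuple(self.marks)
        if len(self.marks) != N_MARKS:
            raise ConfigurationError(
                f"exactly {N_MARKS} marks required, got {len(self.marks)}"
            )
        missing = [m for m in self.marks if m not in self.coverage]
        if missing:
            raise ConfigurationError(f"missing coverage for marks: {missing}")

    # -- queries ------------------------------------------------------------

    def mark_vector_at(self, chrom: str, pos: int) -> np.ndarray:
        """The 8-long binary mark vector at a single genomic position."""
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.genome[chrom]:
            raise ValueError(f"position {pos} outside {chrom} bounds")
        vec = np.zeros(N_MARKS, dtype=np.int8)
        for i, mark in enumerate(self.marks):
            s, e = self.coverage[mark].get(chrom, (np.empty(0, np.int64),) * 2)
            if s.size and _coverage_at(s, e, np.array([pos]))[0]:
                vec[i] = 1
        return vec

    def pattern_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run-length encoding of the 8-bit mark pattern along ``chrom``.

        Returns ``(starts, ends, codes)`` where ``codes`` holds the pattern
        code (bit i = mark i present) constant on each ``[start, end)`` run.
        """
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.genome[chrom]
        empty = (np.empty(0, np.int64), np.empty(0, np.int64))
        sets = [self.coverage[m].get(chrom, empty) for m in self.marks]
        bounds = _segment_bounds(sets, length)
        seg_starts, seg_ends = bounds[:-1], bounds[1:]
        codes = np.zeros(seg_starts.size, dtype=np.int32)
        for i, (s, e) in enumerate(sets):
            if s.size:
                codes |= _coverage_at(s, e, seg_starts).astype(np.int32) << i
        return seg_starts, seg_ends, codes

    def pattern_counts(self) -> np.ndarray:
        """Genome-wide bp count of each of the 256 mark patterns."""
        counts = np.zeros(N_PATTERNS, dtype=np.int64)
        for chrom in self.genome:
            s, e, codes = self.pattern_runs(chrom)
            np.add.at(counts, codes, e - s)
        return counts


def build_mark_trackset(
    sample_files: Mapping[str, Sequence[str | Path]],
    genome: Mapping[str, int],
    tissue_label: str = "",
    marks: Sequence[str] | None = None,
    format: str = "BED",
) -> MarkTrackSet:
    """Build a tissue track set by taking, per mark, the interval union over
    all that mark's samples, clipped to the genome bounds.

    ``sample_files`` maps each mark name to one or more peak files.  All
    eight marks must be present with at least one file each.
    """
    if marks is None:
        marks = tuple(sample_files.keys())
    marks = tuple(marks)
    absent = [m for m in marks if not sample_files.get(m)]
    if len(marks) != N_MARKS or absent:
        raise ConfigurationError(
            f"need {N_MARKS} marks each with >=1 peak file; "
            f"got {len(marks)} marks, missing/empty: {absent}"
        )
    coverage: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for mark in marks:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for path in sample_files[mark]:
            for iv in read_peak_intervals(path, format=format):
                if iv.chrom not in genome:
                    continue
                start = max(iv.start, 0)
                end = min(iv.end, genome[iv.chrom])
                if start < end:
                    per_chrom.setdefault(iv.chrom, []).append((start, end))
        coverage[mark] = {}
        for chrom, pairs in per_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            coverage[mark][chrom] = _merge_arrays(arr[:, 0], arr[:, 1])
    return MarkTrackSet(tissue_label, marks, coverage, dict(genome))


def mark_vector_at(ts: MarkTrackSet, chrom: str, pos: int) -> np.ndarray:
    return ts.mark_vector_at(chrom, pos)


# ---------------------------------------------------------------------------
# Training samples
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    """Mark-pattern observations with bp multiplicities.

    ``pattern_counts[k]`` is the number of basepairs in the (merged) source
    intervals whose 8-bit mark pattern has code ``k``; each bp contributes
    exactly one observation.
    """

    pattern_counts: np.ndarray
    marks: tuple[str, ...]
    source_intervals: tuple[GenomicInterval, ...] = ()
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.pattern_counts = np.asarray(self.pattern_counts, dtype=np.int64)
        if self.pattern_counts.shape != (N_PATTERNS,):
            raise ValueError("pattern_counts must have length 256")
        if (self.pattern_counts < 0).any():
            raise ValueError("negative pattern count")

    @property
    def total_bp(self) -> int:
        return int(self.pattern_counts.sum())

    @property
    def n_distinct_patterns(self) -> int:
        return int((self.pattern_counts > 0).sum())

    @classmethod
    def from_vectors(cls, vectors: np.ndarray,
                     marks: Sequence[str] = DEFAULT_MARKS) -> "TrainingSample":
        """Build from an ``(n, 8)`` binary observation matrix."""
        vectors = np.asarray(vectors)
        if vectors.ndim != 2 or vectors.shape[1] != N_MARKS:
            raise ValueError("vectors must be (n, 8)")
        codes = (vectors.astype(np.int64) << np.arange(N_MARKS)).sum(axis=1)
        counts = np.bincount(codes, minlength=N_PATTERNS)
        return cls(counts, tuple(marks))

    def to_vectors(self) -> np.ndarray:
        """Expand to an explicit (total_bp, 8) binary matrix (small data only)."""
        codes = np.repeat(np.arange(N_PATTERNS), self.pattern_counts)
        return PATTERNS[codes].astype(np.int8)


def build_training_sample(
    seeds: Sequence[tuple[str, int]],
    flank_bp: int,
    ts: MarkTrackSet,
) -> TrainingSample:
    """Expand seed positions into fixed-width windows and collect mark patterns.

    Each seed ``(chrom, pos)`` becomes the window ``[pos - flank_bp,
    pos + flank_bp)`` (default usage: 500 bp flanks, 1 kb total), clipped to
    chromosome bounds.  Overlapping windows are merged so every basepair
    contributes one observation.  Seeds on unknown chromosomes or outside the
    genome are skipped with a warning.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    n_skipped = 0
    for chrom, pos in seeds:
        length = ts.genome.get(chrom)
        if length is None or not 0 <= pos < length:
            n_skipped += 1
            continue
        start = max(pos - flank_bp, 0)
        end = min(pos + flank_bp, length)
        if start < end:
            windows.setdefault(chrom, []).append((start, end))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} seeds outside the genome", stacklevel=2)
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    merged: list[GenomicInterval] = []
    for chrom in sorted(windows):
        arr = np.asarray(windows[chrom], dtype=np.int64)
        w_s, w_e = _merge_arrays(arr[:, 0], arr[:, 1])
        merged.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(w_s, w_e))
        seg_s, seg_e, codes = ts.pattern_runs(chrom)
        # intersect each merged window with the pattern runs
        for a, b in zip(w_s, w_e):
            i0 = int(np.searchsorted(seg_e, a, side="right"))
            i1 = int(np.searchsorted(seg_s, b, side="left"))
            ov = np.minimum(seg_e[i0:i1], b) - np.maximum(seg_s[i0:i1], a)
            np.add.at(counts, codes[i0:i1], ov)
    return TrainingSample(counts, ts.marks, tuple(merged), n_skipped)


# ---------------------------------------------------------------------------
# ScoreTrack
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class ScoreTrack:
    """Run-length-encoded per-bp scores in [0, 1] over a genome.

    ``runs[chrom]`` is ``(starts, ends, values)``; positions not covered by
    any run implicitly score 0.  Runs are sorted, non-overlapping, and
    adjacent runs with equal value are merged.
    """

    genome: dict[str, int]
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_runs(
        cls,
        genome: Mapping[str, int],
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "ScoreTrack":
        """Normalize raw runs: sort, drop empty, merge equal-valued neighbours."""
        norm: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            keep = e > s
            s, e, v = s[keep], e[keep], v[keep]
            if s.size == 0:
                continue
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping score runs on {chrom}")
            # merge book-ended runs with identical value
            new = np.empty(s.size, dtype=bool)
            new[0] = True
            new[1:] = (s[1:] != e[:-1]) | (v[1:] != v[:-1])
            idx = np.flatnonzero(new)
            ms = s[idx]
            me = np.empty_like(ms)
            me[:-1] = e[idx[1:] - 1]
            me[-1] = e[-1]
            norm[chrom] = (ms, me, v[idx])
        return cls(dict(genome), norm)

    @classmethod
    def constant(cls, genome: Mapping[str, int], value: float) -> "ScoreTrack":
        runs = {
            c: (np.array([0]), np.array([length]), np.array([float(value)]))
            for c, length in genome.items()
        }
        return cls.from_runs(genome, runs)

    @classmethod
    def from_dense(cls, genome: Mapping[str, int],
                   dense: Mapping[str, np.ndarray]) -> "ScoreTrack":
        runs = {}
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            runs[chrom] = (starts, ends, arr[starts])
        return cls.from_runs(genome, runs)

    # -- queries ------------------------------------------------------------

    @property
    def total_bp(self) -> int:
        return int(sum(self.genome.values()))

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        s, e, v = self.runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
        if s.size == 0:
            return 0.0
        idx = int(np.searchsorted(s, pos, side="right")) - 1
        if idx >= 0 and pos < e[idx]:
            return float(v[idx])
        return 0.0

    def dense(self, chrom: str) -> np.ndarray:
        """Explicit per-bp score array (toy genomes only)."""
        arr = np.zeros(self.genome[chrom], dtype=np.float64)
        if chrom in self.runs:
            s, e, v = self.runs[chrom]
            for a, b, val in zip(s, e, v):
                arr[a:b] = val
        return arr

    def window_means(self, chrom: str, starts: np.ndarray,
                     ends: np.ndarray) -> np.ndarray:
        """Mean score over each window [start, end), clipped to chromosome
        bounds; uncovered basepairs count as 0."""
        length = self.genome[chrom]
        a = np.clip(np.asarray(starts, dtype=np.int64), 0, length)
        b = np.clip(np.asarray(ends, dtype=np.int64), 0, length)
        width = (b - a).astype(np.float64)
        out = np.zeros(a.shape, dtype=np.float64)
        s, e, v = self.runs.get(
            chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
        )
        if s.size:
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            i0 = np.searchsorted(e, a, side="right")
            i1 = np.searchsorted(s, b, side="left")
            total = cum[i1] - cum[np.minimum(i0, i1)]
            has = i1 > i0
            if has.any():
                first, last = i0[has], i1[has] - 1
                total[has] -= v[first] * np.maximum(a[has] - s[first], 0)
                total[has] -= v[last] * np.maximum(e[last] - b[has], 0)
            out = total
        ok = width > 0
        result = np.zeros(a.shape, dtype=np.float64)
        result[ok] = out[ok] / width[ok]
        return result

    def threshold_intervals(self, cutoff: float) -> list[GenomicInterval]:
        """Merged intervals where score >= cutoff (uncovered bp score 0)."""
        out: list[GenomicInterval] = []
        for chrom in sorted(self.genome):
            length = self.genome[chrom]
            if cutoff <= 0:
                out.append(GenomicInterval(chrom, 0, length))
                continue
            s, e, v = self.runs.get(
                chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
            )
            sel = v >= cutoff
            if sel.any():
                ms, me = _merge_arrays(s[sel], e[sel])
                out.extend(
                    GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me)
                )
        return out

    def equals(self, other: "ScoreTrack", tol: float = 0.0) -> bool:
        if self.genome != other.genome:
            return False
        for chrom in self.genome:
            a = self.runs.get(chrom)
            b = other.runs.get(chrom)
            if (a is None) != (b is None):
                return False
            if a is None:
                continue
            if a[0].size != b[0].size:
                return False
            if not (np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])):
                return False
            if tol == 0.0:
                if not np.array_equal(a[2], b[2]):
                    return False
            elif np.max(np.abs(a[2] - b[2]), initial=0.0) > tol:
                return False
        return True


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    """Write a score track as bedGraph (chrom, start, end, score).

    Adjacent equal-score runs are already merged in the track; scores are
    printed with 17 significant digits so a read-back is bit-identical.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            s, e, v = track.runs[chrom]
            for a, b, val in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{float(val)!r}\n")


def read_score_track(path: str | Path, genome: Mapping[str, int]) -> ScoreTrack:
    """Read a bedGraph score track; positions absent from the file score 0."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise PeakParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            per_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    runs = {}
    for chrom, triples in per_chrom.items():
        triples.sort()
        s = np.array([t[0] for t in triples], dtype=np.int64)
        e = np.array([t[1] for t in triples], dtype=np.int64)
        v = np.array([t[2] for t in triples], dtype=np.float64)
        runs[chrom] = (s, e, v)
    return ScoreTrack.from_runs(genome, runs)


def export_binary_annotation(track: ScoreTrack, cutoff: float) -> list[GenomicInterval]:
    """Binarize a score track at ``cutoff``: merged intervals with score >= cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return track.threshold_intervals(cutoff)
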