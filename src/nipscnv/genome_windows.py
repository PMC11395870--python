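"""Genome windowing on mappability tracks.

Shallow-sequencing CNV callers compare read depth between genomic windows
across samples.  To make window depth comparable, windows are not fixed-width
but hold a *constant expected number of uniquely mappable positions*: a
chromosome is covered by adjacent windows, each accumulating small fixed-size
mappability bins until a per-window quota of uniquely mappable positions is
reached.  Regions of poor mappability therefore yield physically longer
windows with the same expected read count.  The average window length is
~1 Mb by default.

Coordinates are 0-based half-open throughout this package; clinical report
strings convert to 1-based inclusive at the formatting boundary only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "MappabilityTrack",
    "WindowMap",
    "build_windows",
    "uniform_track",
    "read_window_map",
    "write_window_map",
]

DEFAULT_BIN_SIZE = 10_000
DEFAULT_TARGET_AVG_LEN = 1_000_000


@dataclass
class MappabilityTrack:
    """Per-bin uniquely-mappable-position counts and GC, at fixed bin size.

    Bins are non-overlapping, sorted, half-open, and grouped by chromosome in
    genome order.  ``unique_positions`` counts positions whose short
    single-end read maps uniquely; ``gc`` is the GC fraction of the bin.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    unique_positions: np.ndarray
    gc: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.unique_positions = np.asarray(self.unique_positions, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=np.float64)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.unique_positions) == len(self.gc) == n):
            raise ValueError("track columns have unequal lengths")
        if n == 0:
            return
        if np.any(self.end <= self.start):
            raise ValueError("track bins must have end > start")
        if np.any(self.unique_positions < 0) or np.any(self.unique_positions > self.end - self.start):
            raise ValueError("unique_positions must lie in [0, bin length]")
        if np.any(self.gc < 0) or np.any(self.gc > 1):
            raise ValueError("gc must lie in [0, 1]")
        for name, sl in _chrom_slices(self.chrom).items():
            s, e = self.start[sl], self.end[sl]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"track bins overlap or are unsorted on {name}")

    def __len__(self) -> int:
        return len(self.chrom)

    def chrom_order(self) -> list[str]:
        return list(_chrom_slices(self.chrom))


def _chrom_slices(chrom: np.ndarray) -> dict[str, slice]:
    """Contiguous slice per chromosome, preserving genome order.

    Raises if a chromosome appears in more than one contiguous block.
    """
    out: dict[str, slice] = {}
    if len(chrom) == 0:
        return out
    boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(chrom)]))
    for s, e in zip(starts, ends):
        name = chrom[s]
        if name in out:
            raise ValueError(f"chromosome {name} appears in non-contiguous blocks")
        out[name] = slice(int(s), int(e))
    return out


@dataclass
class WindowMap:
    """Ordered genomic windows with expected unique-position mass and GC.

    Windows are adjacent within a chromosome (end of window i equals start of
    window i+1), indexed 0..N-1 in genome order.  Windows with zero expected
    unique positions are unusable (no read-depth signal can be expected) and
    are propagated as missing through the pipeline.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    expected_unique: np.ndarray
    gc: np.ndarray
    genome_build: str = "synthetic"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.expected_unique = np.asarray(self.expected_unique, dtype=np.float64)
        self.gc = np.asarray(self.gc, dtype=np.float64)
        if len(self) and np.any(self.end <= self.start):
            raise ValueError("windows must have end > start")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n(self) -> int:
        return len(self.chrom)

    @property
    def usable(self) -> np.ndarray:
        return self.expected_unique > 0

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_slices(self) -> dict[str, slice]:
        return _chrom_slices(self.chrom)

    def chromosomes(self) -> list[str]:
        return list(self.chrom_slices())

    def equals(self, other: "WindowMap") -> bool:
        return (
            self.genome_build == other.genome_build
            and len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
            and bool(np.allclose(self.expected_unique, other.expected_unique))
            and bool(np.allclose(self.gc, other.gc, atol=1e-9))
        )


def build_windows(track: MappabilityTrack, target_avg_len: int = DEFAULT_TARGET_AVG_LEN) -> WindowMap:
    """Accumulate mappability bins into windows of constant unique-position quota.

    Per chromosome, the number of windows is ``round(chrom_length /
    target_avg_len)`` (at least 1) and the quota is the chromosome's total
    unique positions divided by that number; bins are accumulated until the
    running total crosses each quota multiple, so every window carries the
    same expected unique mass (within one bin) while window *lengths* absorb
    mappability gaps.  Windows never cross chromosome boundaries; the last
    window on a chromosome absorbs any remainder.  A chromosome with zero
    unique positions becomes a single unusable window.
    """
    if len(track) == 0:
        raise ValueError("empty mappability track")
    if target_avg_len < 10 * track.bin_size:
        raise ValueError(f"target_avg_len must be >= 10 x bin size ({10 * track.bin_size})")

    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    out_eu: list[float] = []
    out_gc: list[float] = []

    for name, sl in _chrom_slices(track.chrom).items():
        starts = track.start[sl]
        ends = track.end[sl]
        uniq = track.unique_positions[sl].astype(np.float64)
        gc = track.gc[sl]
        chrom_len = int(ends[-1] - starts[0])
        total = float(uniq.sum())

        if total == 0:
            out_chrom.append(name)
            out_start.append(int(starts[0]))
            out_end.append(int(ends[-1]))
            out_eu.append(0.0)
            out_gc.append(float(gc.mean()))
            continue

        n_win = max(1, round(chrom_len / target_avg_len))
        cum = np.cumsum(uniq)
        # first bin index at which the running total reaches each quota multiple
        quota_marks = total / n_win * np.arange(1, n_win)
        cut_bins = np.searchsorted(cum, quota_marks, side="left")
        cut_bins = np.unique(cut_bins)  # a huge bin may cross several quotas
        bounds = np.concatenate(([-1], cut_bins, [len(uniq) - 1]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            b0, b1 = int(lo) + 1, int(hi) + 1  # bin index range [b0, b1)
            w_uniq = uniq[b0:b1]
            eu = float(w_uniq.sum())
            if eu > 0:
                w_gc = float(np.average(gc[b0:b1], weights=w_uniq))
            else:
                w_gc = float(gc[b0:b1].mean())
            out_chrom.append(name)
            out_start.append(int(starts[b0]))
            out_end.append(int(ends[b1 - 1]))
            out_eu.append(eu)
            out_gc.append(w_gc)

    return WindowMap(
        chrom=np.array(out_chrom, dtype=object),
        start=np.array(out_start),
        end=np.array(out_end),
        expected_unique=np.array(out_eu),
        gc=np.array(out_gc),
        genome_build=getattr(track, "genome_build", "synthetic"),
    )


GCSpec = float | Callable[[str, int], float]


def uniform_track(
    genome_spec: Sequence[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc: GCSpec = 0.41,
) -> MappabilityTrack:
    """Fully mappable track for a synthetic genome.

    ``genome_spec`` lists (chromosome, length) pairs; lengths must be
    multiples of ``bin_size``.  ``gc`` is either a constant fraction or a
    callable ``gc(chrom, bin_midpoint_bp) -> fraction``.
    """
    if not genome_spec:
        raise ValueError("empty genome_spec")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in genome_spec:
        if length <= 0 or length % bin_size != 0:
            raise ValueError(f"length of {name} must be a positive multiple of bin_size")
        n = length // bin_size
        chroms.extend([name] * n)
        s = np.arange(n, dtype=np.int64) * bin_size
        starts.extend(s.tolist())
        ends.extend((s + bin_size).tolist())
    start_arr = np.array(starts)
    end_arr = np.array(ends)
    chrom_arr = np.array(chroms, dtype=object)
    if callable(gc):
        mids = (start_arr + end_arr) // 2
        gc_arr = np.array([gc(c, int(m)) for c, m in zip(chrom_arr, mids)])
    else:
        gc_arr = np.full(len(chrom_arr), float(gc))
    return MappabilityTrack(
        chrom=chrom_arr,
        start=start_arr,
        end=end_arr,
        unique_positions=np.full(len(chrom_arr), bin_size, dtype=np.int64),
        gc=gc_arr,
        bin_size=bin_size,
    )


_WINDOW_COLUMNS = ["chrom", "start", "end", "expected_unique", "gc"]


def write_window_map(wmap: WindowMap, path) -> None:
    """Write a window map as TSV with a genome-build header line."""
    with open(path, "w") as fh:
        fh.write(f"#genome_build={wmap.genome_build}\n")
        fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
        for i in range(len(wmap)):
            fh.write(
                f"{wmap.chrom[i]}\t{wmap.start[i]}\t{wmap.end[i]}\t"
                f"{wmap.expected_unique[i]:.6g}\t{wmap.gc[i]:.6f}\n"
            )


def read_window_map(path) -> WindowMap:
    """Read a window map TSV, validating sortedness and non-overlap.

    Raises ``ValueError`` naming the first offending line on unsorted or
    overlapping rows.
    """
    build = "synthetic"
    rows: list[tuple[str, int, int, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome_build="):
                    build = line.split("=", 1)[1]
                continue
            if line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_WINDOW_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(_WINDOW_COLUMNS)} columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3]), float(parts[4])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            c, s, e = parts[0], int(parts[1]), int(parts[2])
            if len(rows) >= 2:
                pc, ps, pe = rows[-2][0], rows[-2][1], rows[-2][2]
                if c == pc and s < pe:
                    kind = "overlaps" if s > ps else "is unsorted relative to"
                    raise ValueError(f"line {lineno}: window {c}:{s}-{e} {kind} previous window")
    chrom = np.array([r[0] for r in rows], dtype=object)
    _chrom_slices(chrom)  # rejects interleaved chromosome blocks
    return WindowMap(
        chrom=chrom,
        start=np.array([r[1] for r in rows], dtype=np.int64),
        end=np.array([r[2] for r in rows], dtype=np.int64),
        expected_unique=np.array([r[3] for r in rows]),
        gc=np.array([r[4] for r in rows]),
        genome_build=build,
    )
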