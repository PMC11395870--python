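"""Alignment filtering and per-window read counting.

Only "unique reads" (URs) enter the depth signal: mapped, non-duplicate,
non-secondary/supplementary primary alignments with mapping quality at or
above a uniqueness proxy threshold and at most a small number of mismatches.
Each retained read is assigned to the window containing its leftmost aligned
base.  chrY reads and the genome-wide UR total are tallied separately because
fetal-fraction estimation and QC need them even when the corresponding
contigs carry no windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .genome_windows import WindowMap

__all__ = [
    "FilterParams",
    "SampleCounts",
    "filter_alignment",
    "count_sample",
    "read_counts",
    "write_counts",
]

log = logging.getLogger("nipscnv")

CHRY_NAMES = frozenset({"chrY", "Y"})


@dataclass(frozen=True)
class FilterParams:
    """Unique-read filter.

    ``min_mapq`` operationalizes "uniquely aligned" (multi-mappers get MAPQ 0
    from standard aligners); ``max_mismatches`` bounds the NM tag for short
    (50 bp) single-end reads.  A missing NM tag passes, permissively.
    """

    min_mapq: int = 30
    max_mismatches: int = 2
    drop_duplicates: bool = True
    drop_unmapped: bool = True
    drop_secondary_supplementary: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.max_mismatches < 0:
            raise ValueError("min_mapq and max_mismatches must be >= 0")


@dataclass
class SampleCounts:
    """Raw per-window UR counts for one sample plus genome-wide tallies."""

    sample_id: str
    raw: np.ndarray
    total_unique_reads: int
    chry_reads: int = 0
    batch_id: str = ""
    reported_sex_karyotype: Optional[str] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.int64)
        if np.any(self.raw < 0):
            raise ValueError("counts must be >= 0")
        if self.total_unique_reads < 0 or self.chry_reads < 0:
            raise ValueError("read totals must be >= 0")


def filter_alignment(record: pysam.AlignedSegment, params: FilterParams = FilterParams()) -> tuple[bool, str]:
    """Keep/drop decision for one alignment record.

    Returns ``(keep, reason)``; the reason names the first failed criterion,
    or ``"pass"``.  Paired-end inputs are counted from read 1 only (the
    pipeline assumes single-end 50 bp reads).
    """
    if params.drop_unmapped and record.is_unmapped:
        return False, "unmapped"
    if params.drop_secondary_supplementary and record.is_secondary:
        return False, "secondary"
    if params.drop_secondary_supplementary and record.is_supplementary:
        return False, "supplementary"
    if params.drop_duplicates and record.is_duplicate:
        return False, "duplicate"
    if record.is_qcfail:
        return False, "low_quality"
    if record.is_paired and record.is_read2:
        return False, "read2"
    if record.mapping_quality < params.min_mapq:
        return False, "low_mapq"
    try:
        nm = record.get_tag("NM")
    except KeyError:
        nm = None  # permissive: missing mismatch tag passes
    if nm is not None and nm > params.max_mismatches:
        return False, "mismatches"
    return True, "pass"


def count_sample(
    alignments,
    windows: WindowMap,
    params: FilterParams = FilterParams(),
    sample_id: str = "sample",
    batch_id: str = "",
) -> SampleCounts:
    """Count retained reads per window from a SAM file path or pysam iterable.

    Reads on contigs absent from the window map still contribute to
    ``total_unique_reads`` (and ``chry_reads`` for chrY) but to no window.
    A read starting exactly on a window boundary belongs to the right-hand
    window (half-open convention).
    """
    close_me = None
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        close_me = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        stream: Iterable[pysam.AlignedSegment] = close_me
    else:
        stream = alignments

    slices = windows.chrom_slices()
    starts_by_chrom = {name: (windows.start[sl], windows.end[sl], sl.start) for name, sl in slices.items()}

    raw = np.zeros(len(windows), dtype=np.int64)
    total = 0
    chry = 0
    missing_nm_seen = False
    try:
        for record in stream:
            keep, _reason = filter_alignment(record, params)
            if not keep:
                continue
            if not missing_nm_seen and not record.has_tag("NM"):
                missing_nm_seen = True
                log.warning("sample %s: records without NM tag pass the mismatch filter", sample_id)
            total += 1
            chrom = record.reference_name
            if chrom in CHRY_NAMES:
                chry += 1
            entry = starts_by_chrom.get(chrom)
            if entry is None:
                continue
            w_start, w_end, offset = entry
            pos = record.reference_start  # leftmost aligned base, 0-based
            i = int(np.searchsorted(w_start, pos, side="right")) - 1
            if i >= 0 and pos < w_end[i]:
                raw[offset + i] += 1
    finally:
        if close_me is not None:
            close_me.close()

    if total == 0:
        raise ValueError(f"empty sample: no reads retained for {sample_id}")
    return SampleCounts(sample_id=sample_id, raw=raw, total_unique_reads=total, chry_reads=chry, batch_id=batch_id)


def write_counts(samples: list[SampleCounts], windows: WindowMap, path) -> None:
    """Write a count matrix TSV: one row per window, one column per sample.

    A metadata header block carries per-sample totals so the file round-trips
    losslessly.
    """
    for s in samples:
        if len(s.raw) != len(windows):
            raise ValueError(f"sample {s.sample_id}: {len(s.raw)} counts vs {len(windows)} windows")
    with open(path, "w") as fh:
        fh.write(f"#n_windows={len(windows)}\n")
        for s in samples:
            sex = s.reported_sex_karyotype or ""
            fh.write(
                f"#sample\t{s.sample_id}\ttotal_unique_reads={s.total_unique_reads}\t"
                f"chry_reads={s.chry_reads}\tbatch_id={s.batch_id}\tsex={sex}\n"
            )
        fh.write("chrom\tstart\tend" + "".join(f"\t{s.sample_id}" for s in samples) + "\n")
        for i in range(len(windows)):
            fh.write(
                f"{windows.chrom[i]}\t{windows.start[i]}\t{windows.end[i]}"
                + "".join(f"\t{s.raw[i]}" for s in samples)
                + "\n"
            )


def read_counts(path, windows: Optional[WindowMap] = None) -> list[SampleCounts]:
    """Read a count matrix TSV written by :func:`write_counts`."""
    meta: list[dict] = []
    n_windows = None
    sample_ids: list[str] = []
    matrix: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#n_windows="):
                n_windows = int(line.split("=", 1)[1])
                continue
            if line.startswith("#sample\t"):
                parts = line.split("\t")
                entry = {"sample_id": parts[1]}
                for kv in parts[2:]:
                    k, _, v = kv.partition("=")
                    entry[k] = v
                meta.append(entry)
                continue
            if line.startswith("#"):
                continue
            if line.startswith("chrom\t"):
                sample_ids = line.split("\t")[3:]
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(sample_ids):
                raise ValueError(f"line {lineno}: expected {3 + len(sample_ids)} columns")
            matrix.append([int(x) for x in parts[3:]])

    if n_windows is not None and len(matrix) != n_windows:
        raise ValueError(f"file declares {n_windows} windows but has {len(matrix)} rows")
    if windows is not None and len(matrix) != len(windows):
        raise ValueError(f"count rows ({len(matrix)}) do not match window map ({len(windows)})")
    by_id = {m["sample_id"]: m for m in meta}
    arr = np.array(matrix, dtype=np.int64).reshape(len(matrix), len(sample_ids))
    out: list[SampleCounts] = []
    for j, sid in enumerate(sample_ids):
        m = by_id.get(sid, {})
        out.append(
            SampleCounts(
                sample_id=sid,
                raw=arr[:, j] if len(matrix) else np.zeros(0, dtype=np.int64),
                total_unique_reads=int(m.get("total_unique_reads", arr[:, j].sum() if len(matrix) else 0)),
                chry_reads=int(m.get("chry_reads", 0)),
                batch_id=m.get("batch_id", ""),
                reported_sex_karyotype=m.get("sex") or None,
            )
        )
    return out
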