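"""Chromosome-level Z-test for fetal trisomy/monosomy screening.

Each sample's per-chromosome representation — the fraction of its
GC-corrected reads falling on that chromosome — is compared against the
other samples in the same sequencing lot.  A whole-chromosome trisomy at
fetal fraction ff shifts the chromosome's dosage to 1 + ff/2, which at
typical depths moves the representation by many standard deviations of the
lot scatter.  Calls are made at |z| >= 3 (industry convention); samples
below the minimum fetal-fraction gate are reported no-call rather than
negative, because an undetectable fetal complement cannot produce a
trustworthy negative.  The lot statistics reuse the same leave-one-out,
outlier-trimmed machinery as the window-level caller.  Sex-chromosome z
values are reported without karyotype interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cnv_hmm import trimmed_stats
from .fetal_fraction import FFEstimate
from .gc_correct import CorrectedCounts
from .genome_windows import WindowMap

__all__ = ["ChromRepresentation", "AneuploidyResult", "chromosome_representation", "batch_aneuploidy_z"]

log = logging.getLogger("nipscnv")


@dataclass
class ChromRepresentation:
    sample_id: str
    chroms: list[str]
    fractions: np.ndarray  # sums to 1 over included chromosomes

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)


@dataclass
class AneuploidyResult:
    sample_id: str
    chroms: list[str]
    z: np.ndarray
    calls: list[tuple[str, str]] = field(default_factory=list)  # (chrom, "gain"|"loss")
    z_threshold: float = 3.0
    no_call: bool = False
    untestable: list[str] = field(default_factory=list)


def chromosome_representation(
    crn: CorrectedCounts,
    windows: WindowMap,
    include: Optional[Sequence[str]] = None,
) -> ChromRepresentation:
    """Per-chromosome CRN fraction over usable windows.

    ``include`` restricts (and orders) the chromosomes entering the
    denominator; by default every chromosome in the map is included.  A
    chromosome whose windows are all unusable is excluded with a warning.
    """
    if len(crn.crn) != len(windows):
        raise ValueError("sample does not match the window map")
    slices = windows.chrom_slices()
    names = list(include) if include is not None else list(slices)
    chroms: list[str] = []
    sums: list[float] = []
    for name in names:
        sl = slices.get(name)
        if sl is None:
            raise ValueError(f"chromosome {name} not in window map")
        vals = crn.crn[sl]
        if not np.any(np.isfinite(vals)):
            log.warning("sample %s: chromosome %s has no usable windows; excluded", crn.sample_id, name)
            continue
        chroms.append(name)
        sums.append(float(np.nansum(vals)))
    total = sum(sums)
    if total <= 0:
        raise ValueError(f"sample {crn.sample_id}: zero CRN over included chromosomes")
    return ChromRepresentation(sample_id=crn.sample_id, chroms=chroms, fractions=np.array(sums) / total)


def batch_aneuploidy_z(
    representations: Sequence[ChromRepresentation],
    ff_estimates: Optional[Sequence[FFEstimate]] = None,
    z_threshold: float = 3.0,
    min_ff: float = 0.035,
    call_chroms: Optional[Sequence[str]] = None,
    min_batch: int = 8,
    force: bool = False,
    outlier_z: float = 3.0,
) -> list[AneuploidyResult]:
    """Leave-one-out lot Z per chromosome and sample, with calls at |z| >= threshold.

    Samples whose chrY-based fetal fraction is known and below ``min_ff``
    are flagged no-call (gated), not tested.  A chromosome with zero lot SD
    is untestable.  ``call_chroms`` limits which chromosomes generate calls
    (z is still reported for all; sex chromosomes are typically excluded
    from calling).
    """
    n = len(representations)
    if n < min_batch and not force:
        raise ValueError(f"batch has {n} samples; need >= {min_batch} (or force)")
    if n < 2:
        raise ValueError("need at least 2 samples")
    chroms = representations[0].chroms
    for r in representations:
        if r.chroms != chroms:
            raise ValueError("samples have inconsistent chromosome sets")
    x = np.vstack([r.fractions for r in representations])
    mean, sd, kept = trimmed_stats(x, outlier_z=outlier_z)
    n_kept = kept.sum(axis=0)
    s = np.where(kept, x, 0.0).sum(axis=0)
    ss = np.where(kept, x**2, 0.0).sum(axis=0)

    callable_set = set(call_chroms) if call_chroms is not None else set(chroms)
    ff_by_idx: dict[int, FFEstimate] = {}
    if ff_estimates is not None:
        ff_by_idx = dict(enumerate(ff_estimates))

    results: list[AneuploidyResult] = []
    for i, rep in enumerate(representations):
        xi = x[i]
        in_c = kept[i]
        n1 = n_kept - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            loo_mean = (s - np.where(in_c, xi, 0.0)) / np.maximum(n1, 1)
            loo_var = (ss - np.where(in_c, xi**2, 0.0) - n1 * loo_mean**2) / np.maximum(n1 - 1, 1)
        m = np.where(in_c & (n1 >= 3), loo_mean, mean)
        v = np.where(in_c & (n1 >= 3), np.maximum(loo_var, 0.0), sd**2)
        sdv = np.sqrt(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (xi - m) / sdv
        untestable = [c for c, bad in zip(chroms, ~(sdv > 0)) if bad]
        z[~(sdv > 0)] = np.nan

        ff = ff_by_idx.get(i)
        gated = ff is not None and ff.method == "chrY" and ff.ff is not None and ff.ff < min_ff
        calls: list[tuple[str, str]] = []
        if not gated:
            for c, zc in zip(chroms, z):
                if c in callable_set and np.isfinite(zc) and abs(zc) >= z_threshold:
                    calls.append((c, "gain" if zc > 0 else "loss"))
        else:
            log.info("sample %s: fetal fraction below gate; aneuploidy no-call", rep.sample_id)
        results.append(
            AneuploidyResult(
                sample_id=rep.sample_id,
                chroms=chroms,
                z=z,
                calls=calls,
                z_threshold=z_threshold,
                no_call=gated,
                untestable=untestable,
            )
        )
    return results
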