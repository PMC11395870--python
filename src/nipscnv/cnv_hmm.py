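"""Per-window batch Z-scores and HMM copy-number decoding.

The caller compares each sample's GC-corrected window counts (CRN) against
the other samples of the same sequencing lot:

    Z_win = (CRN_win - CRN_mean) / SD_CRN

with CRN_mean and SD_CRN the per-window mean and (n-1)-denominator standard
deviation over the lot.  Two robustness measures are layered on the plain
formula, both motivated by desk-scale lot sizes:

* leave-one-out: a sample is excluded from its own reference statistics,
  so its signal cannot shrink the very deviation being tested;
* outlier trimming: samples whose first-pass |Z| exceeds a cutoff at a
  window are excluded from that window's second-pass statistics, so one
  CNV-carrying lot mate cannot inflate SD_CRN and mask another.

Before any of this, each sample's CRN vector is rescaled to the lot median
total, making samples at different sequencing depths comparable.

Z profiles are discretized into five symbols (strong/weak loss, neutral,
weak/strong gain) and decoded per chromosome by a three-state
(loss/neutral/gain) discrete-emission hidden Markov model via Viterbi
dynamic programming in log space.  Maximal runs of non-neutral states become
segments, filtered on |mean Z| and matched against a catalog of known
pathogenic microdeletion/microduplication regions.  A fetal heterozygous
event shifts dosage by only ff/2, so the emission and transition defaults
are tuned to flip on one or two strongly deviant windows while keeping a
euploid genome quiet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .fetal_fraction import FFEstimate
from .gc_correct import CorrectedCounts
from .genome_windows import WindowMap

__all__ = [
    "BatchStats",
    "ZProfile",
    "HMMParams",
    "CNVSegment",
    "SyndromeRegion",
    "ScreenResult",
    "normalize_totals",
    "batch_stats",
    "z_scores",
    "discretize",
    "viterbi",
    "decode_states",
    "segment",
    "match_syndromes",
    "load_catalog",
    "screen_sample",
]

log = logging.getLogger("nipscnv")

MIN_BATCH = 8
SYMBOLS = ("S--", "S-", "S0", "S+", "S++")
STATES = ("loss", "neutral", "gain")
LOSS, NEUTRAL, GAIN = 0, 1, 2
_TIEBREAK = (NEUTRAL, LOSS, GAIN)  # conservative screening posture


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------

def normalize_totals(corrected: Sequence[CorrectedCounts]) -> list[CorrectedCounts]:
    """Rescale each sample's CRN vector to the lot median CRN total."""
    totals = np.array([c.total for c in corrected])
    if np.any(totals <= 0):
        bad = corrected[int(np.argmin(totals))].sample_id
        raise ValueError(f"sample {bad}: non-positive CRN total")
    target = float(np.median(totals))
    out = []
    for c, t in zip(corrected, totals):
        out.append(
            CorrectedCounts(
                sample_id=c.sample_id,
                crn=c.crn * (target / t),
                total_unique_reads=c.total_unique_reads,
                chry_reads=c.chry_reads,
                batch_id=c.batch_id,
                model=c.model,
            )
        )
    return out


@dataclass
class BatchStats:
    """Per-window lot statistics with enough state for leave-one-out Z.

    ``kept`` marks which samples survived outlier trimming at each window;
    ``sum``/``sumsq`` are over kept samples only.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_samples: int
    n_kept: np.ndarray
    sum: np.ndarray
    sumsq: np.ndarray
    kept: np.ndarray  # (n_samples, n_windows) bool
    usable: np.ndarray
    sample_ids: list[str]
    batch_id: str = ""


def _masked_mean_sd(x: np.ndarray, kept: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = kept.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(kept, x, 0.0).sum(axis=0)
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        dev2 = np.where(kept, (x - mean) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(np.where(n > 1, dev2 / np.maximum(n - 1, 1), np.nan))
    return mean, sd


def trimmed_stats(matrix: np.ndarray, outlier_z: float = 3.0, passes: int = 5):
    """Iteratively outlier-trimmed column mean/SD (n-1 denominator).

    ``matrix`` is samples x variables; NaN entries are ignored.  Each round
    recomputes the statistics over the kept samples and drops samples whose
    |z| against them exceeds ``outlier_z``, until the kept set converges (or
    ``passes`` rounds); the returned mean/SD always correspond to the final
    kept set.  Two lot mates carrying the same CNV need more than one round:
    the first outlier removed unmasks the second.  Returns (mean, sd, kept).
    Shared by the window-level caller and the chromosome-level Z-test.
    """
    x = np.asarray(matrix, dtype=float)
    kept = np.isfinite(x)
    for _ in range(passes):
        mean, sd = _masked_mean_sd(x, kept)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mean) / sd
        new_kept = np.isfinite(x) & ~(np.abs(z) > outlier_z)
        if np.array_equal(new_kept, kept):
            break
        kept = new_kept
    mean, sd = _masked_mean_sd(x, kept)
    return mean, sd, kept


def batch_stats(
    corrected: Sequence[CorrectedCounts],
    windows: Optional[WindowMap] = None,
    min_samples: int = MIN_BATCH,
    force: bool = False,
    outlier_z: float = 3.0,
    dispersion_outlier_factor: float = 10.0,
    batch_id: str = "",
) -> BatchStats:
    """Per-window trimmed mean/SD over the lot.

    Windows with zero SD, too few contributing samples, or an index of
    dispersion (SD^2 / mean; ~1 under Poisson counting noise regardless of
    window mass) beyond ``dispersion_outlier_factor`` times the lot median
    are flagged unusable.  Fewer than ``min_samples`` samples is an error
    unless forced.
    """
    n = len(corrected)
    if n < 2:
        raise ValueError("batch statistics need at least 2 samples")
    if n < min_samples and not force:
        raise ValueError(f"batch has {n} samples; need >= {min_samples} (or force)")
    lengths = {len(c.crn) for c in corrected}
    if len(lengths) != 1:
        raise ValueError("samples have unequal window counts")
    if windows is not None and lengths.pop() != len(windows):
        raise ValueError("samples do not match the window map")

    x = np.vstack([c.crn for c in corrected])
    mean, sd, kept = trimmed_stats(x, outlier_z=outlier_z)
    n_kept = kept.sum(axis=0)
    s = np.where(kept, x, 0.0).sum(axis=0)
    ss = np.where(kept, x**2, 0.0).sum(axis=0)

    usable = np.isfinite(mean) & np.isfinite(sd) & (sd > 0) & (n_kept >= 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(usable & (mean > 0), sd**2 / mean, np.nan)
    if np.any(usable):
        cap = dispersion_outlier_factor * np.nanmedian(dispersion)
        usable &= ~(dispersion > cap)
    if windows is not None:
        usable &= windows.usable

    return BatchStats(
        mean=mean,
        sd=sd,
        n_samples=n,
        n_kept=n_kept,
        sum=s,
        sumsq=ss,
        kept=kept,
        usable=usable,
        sample_ids=[c.sample_id for c in corrected],
        batch_id=batch_id,
    )


@dataclass
class ZProfile:
    sample_id: str
    z: np.ndarray  # NaN where unusable

    def __len__(self) -> int:
        return len(self.z)


def z_scores(sample: CorrectedCounts, stats: BatchStats, sample_index: Optional[int] = None) -> ZProfile:
    """Z_win = (CRN_win - CRN_mean) / SD_CRN.

    With ``sample_index`` given (the sample's position in the lot), the
    reference mean/SD are recomputed leaving that sample out wherever it
    contributed, from the stored sums.
    """
    x = np.asarray(sample.crn, dtype=float)
    if len(x) != len(stats.mean):
        raise ValueError("sample does not match batch statistics")
    mean = stats.mean.copy()
    sd = stats.sd.copy()
    if sample_index is not None:
        in_w = stats.kept[sample_index] & np.isfinite(x)
        n1 = stats.n_kept - 1  # kept count without this sample
        with np.errstate(invalid="ignore", divide="ignore"):
            loo_mean = (stats.sum - np.where(in_w, x, 0.0)) / np.maximum(n1, 1)
            loo_ss = stats.sumsq - np.where(in_w, x**2, 0.0)
            loo_var = (loo_ss - n1 * loo_mean**2) / np.maximum(n1 - 1, 1)
        ok = in_w & (n1 >= 3)
        mean[ok] = loo_mean[ok]
        sd[ok] = np.sqrt(np.maximum(loo_var[ok], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[~stats.usable] = np.nan
    z[~np.isfinite(x)] = np.nan
    z[~np.isfinite(z)] = np.nan
    return ZProfile(sample_id=sample.sample_id, z=z)


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------

def _neutral_emissions(cuts: Sequence[float]) -> np.ndarray:
    """Standard-normal mass in each Z bin: a euploid window's symbol law."""
    edges = np.concatenate(([-np.inf], np.asarray(cuts, dtype=float), [np.inf]))
    cdf = norm.cdf(edges)
    return np.diff(cdf)


@dataclass
class HMMParams:
    """Three-state, five-symbol discrete HMM over binned Z-scores."""

    cuts: tuple[float, ...] = (-4.0, -2.5, 2.5, 4.0)
    emission: np.ndarray = None
    transition: np.ndarray = None
    initial: np.ndarray = None

    def __post_init__(self) -> None:
        if self.emission is None:
            # Opposite-extreme symbol (S++ under loss, S-- under gain) gets
            # less mass than the *neutral* state's own far tail: a window
            # deviating 4 SD against the event's direction is better
            # explained by euploidy than by the event, so an event run never
            # absorbs a strong opposite-signed window.
            loss = np.array([0.45, 0.35, 0.18999, 0.01, 1e-5])
            neutral = _neutral_emissions(self.cuts)
            self.emission = np.vstack([loss, neutral, loss[::-1]])
        if self.transition is None:
            # Loss/gain self-transition 0.7: sticky enough to bridge one
            # weak window inside a real event, but not so sticky that a
            # decoded run extends across neutral windows and dilutes the
            # run mean below the segment filter.
            self.transition = np.array(
                [
                    [0.70, 0.30, 0.00],
                    [0.001, 0.998, 0.001],
                    [0.00, 0.30, 0.70],
                ]
            )
        if self.initial is None:
            self.initial = np.array([0.001, 0.998, 0.001])
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.cuts) != self.emission.shape[1] - 1:
            raise ValueError("number of cuts must be one less than number of symbols")
        if list(self.cuts) != sorted(self.cuts) or len(set(self.cuts)) != len(self.cuts):
            raise ValueError("cuts must be strictly increasing")
        for name, mat in (("emission", self.emission), ("transition", self.transition)):
            if np.any(mat < 0):
                raise ValueError(f"{name} probabilities must be >= 0")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if np.any(self.initial < 0) or not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must be a probability vector")


def discretize(z: np.ndarray | ZProfile, cuts: Sequence[float] = (-4.0, -2.5, 2.5, 4.0)) -> tuple[np.ndarray, np.ndarray]:
    """Bin Z into symbols; returns (symbols, missing_mask).

    Boundary convention: a Z exactly on a negative cut takes the more
    extreme (left) symbol, a Z exactly on a positive cut the more extreme
    (right) one, so |z| = cut counts as evidence.  Missing windows emit the
    neutral symbol and are flagged in the mask.
    """
    c = list(cuts)
    if c != sorted(c) or len(set(c)) != len(c):
        raise ValueError("cuts must be strictly increasing")
    zv = z.z if isinstance(z, ZProfile) else np.asarray(z, dtype=float)
    missing = ~np.isfinite(zv)
    zf = np.where(missing, 0.0, zv)
    sym = np.select(
        [zf <= c[0], zf <= c[1], zf < c[2], zf < c[3]],
        [0, 1, 2, 3],
        default=4,
    ).astype(np.int64)
    sym[missing] = 2
    return sym, missing


def viterbi(symbols: np.ndarray, params: HMMParams = None) -> np.ndarray:
    """Maximum-a-posteriori state path by log-space dynamic programming.

    Ties are broken deterministically preferring neutral, then loss, then
    gain.  A symbol with zero emission probability under every state is an
    error ("impossible emission").
    """
    if params is None:
        params = HMMParams()
    sym = np.asarray(symbols, dtype=np.int64)
    if len(sym) == 0:
        return np.zeros(0, dtype=np.int64)
    n_states, n_sym = params.emission.shape
    if np.any(sym < 0) or np.any(sym >= n_sym):
        raise ValueError("symbol outside alphabet")
    with np.errstate(divide="ignore"):
        logE = np.log(params.emission)
        logT = np.log(params.transition)
        logI = np.log(params.initial)

    T = len(sym)
    delta = logI + logE[:, sym[0]]
    if not np.any(np.isfinite(delta)):
        raise ValueError("impossible emission at position 0")
    back = np.zeros((T, n_states), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(n_states)
        for j in range(n_states):
            best_i, best_v = _TIEBREAK[0], -np.inf
            for i in _TIEBREAK:
                v = delta[i] + logT[i, j]
                if v > best_v:
                    best_v, best_i = v, i
            back[t, j] = best_i
            new[j] = best_v + logE[j, sym[t]]
        delta = new
        if not np.any(np.isfinite(delta)):
            raise ValueError(f"impossible emission at position {t}")

    best_j, best_v = _TIEBREAK[0], -np.inf
    for j in _TIEBREAK:
        if delta[j] > best_v:
            best_v, best_j = delta[j], j
    path = np.empty(T, dtype=np.int64)
    path[-1] = best_j
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_states(z: ZProfile, windows: WindowMap, params: HMMParams = None) -> np.ndarray:
    """Viterbi decode per chromosome (the HMM never crosses a boundary)."""
    if params is None:
        params = HMMParams()
    path = np.full(len(windows), NEUTRAL, dtype=np.int64)
    for _name, sl in windows.chrom_slices().items():
        sym, _missing = discretize(z.z[sl], params.cuts)
        path[sl] = viterbi(sym, params)
    return path


# ---------------------------------------------------------------------------
# Segmentation and syndrome matching
# ---------------------------------------------------------------------------

@dataclass
class CNVSegment:
    """A decoded loss/gain run, window-aligned; coordinates 0-based half-open
    internally (reports convert to 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    state: str  # "loss" | "gain"
    n_windows: int
    mean_z: float
    syndrome: Optional[str] = None
    syndrome_overlap: float = 0.0
    classification: str = "unmatched"

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_mb(self) -> float:
        return round(self.size_bp / 1e6, 2)


def segment(
    path: np.ndarray,
    z: ZProfile,
    windows: WindowMap,
    min_abs_seg_z: float = 3.0,
    weak_z: float = 2.5,
) -> list[CNVSegment]:
    """Decoded loss/gain runs as segments, with boundary refinement.

    The decoder occasionally annexes a strong event's noisy neighbors, or
    bridges two unrelated deviant windows across neutral ones, so a decoded
    run is refined before reporting:

    * the run is split at interior windows carrying no evidence in the
      run's direction (signed Z short of ``weak_z``);
    * each piece's flanks are trimmed back to the outermost window with
      strong signed evidence (``min_abs_seg_z``), unless no window in the
      piece is that strong — then the piece is left whole so aggregate
      evidence can still carry it;
    * a run with no evidence window at all is kept whole (same rationale).

    A surviving piece must reach ``min_abs_seg_z`` in Stouffer-combined Z
    (sum of window Z over sqrt of window count; the window Z itself for a
    single window), rejecting marginal runs promoted by emission-parameter
    quirks without letting weak flanks veto a strong window.
    """
    segs: list[CNVSegment] = []
    for name, sl in windows.chrom_slices().items():
        p = path[sl]
        zz = z.z[sl]
        starts = windows.start[sl]
        ends = windows.end[sl]
        i = 0
        while i < len(p):
            if p[i] == NEUTRAL:
                i += 1
                continue
            j = i
            while j + 1 < len(p) and p[j + 1] == p[i]:
                j += 1
            state = p[i]
            direction = -1.0 if state == LOSS else 1.0
            signed = direction * zz[i : j + 1]
            evidence = np.isfinite(signed) & (signed >= weak_z)
            pieces: list[tuple[int, int]] = []
            if not np.any(evidence):
                pieces.append((i, j))
            else:
                a = None
                for k, ev in enumerate(evidence):
                    if ev and a is None:
                        a = k
                    elif not ev and a is not None:
                        pieces.append((i + a, i + k - 1))
                        a = None
                if a is not None:
                    pieces.append((i + a, i + len(evidence) - 1))
            for a, b in pieces:
                strong = np.isfinite(zz[a : b + 1]) & (direction * zz[a : b + 1] >= min_abs_seg_z)
                if np.any(strong):
                    while a < b and not (np.isfinite(zz[a]) and direction * zz[a] >= min_abs_seg_z):
                        a += 1
                    while b > a and not (np.isfinite(zz[b]) and direction * zz[b] >= min_abs_seg_z):
                        b -= 1
                run_z = zz[a : b + 1]
                finite = np.isfinite(run_z)
                if not np.any(finite):
                    continue
                mean_z = float(np.nanmean(run_z))
                stouffer = float(np.nansum(run_z) / np.sqrt(finite.sum()))
                if abs(stouffer) >= min_abs_seg_z:
                    segs.append(
                        CNVSegment(
                            chrom=name,
                            start=int(starts[a]),
                            end=int(ends[b]),
                            state=STATES[state],
                            n_windows=b - a + 1,
                            mean_z=mean_z,
                        )
                    )
            i = j + 1
    return segs


@dataclass(frozen=True)
class SyndromeRegion:
    """A known causative CNV region (0-based half-open coordinates)."""

    name: str
    chrom: str
    start: int
    end: int
    expected_state: str  # "loss" | "gain"
    min_overlap: float = 0.5
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name}: end must exceed start")
        if not (0 < self.min_overlap <= 1):
            raise ValueError(f"region {self.name}: min_overlap must be in (0, 1]")


def load_catalog(path=None) -> list[SyndromeRegion]:
    """Load a syndrome-region catalog TSV; default is the packaged catalog."""
    if path is None:
        ref = resources.files("nipscnv").joinpath("data/syndromes.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    build = "GRCh37"
    regions: list[SyndromeRegion] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#genome_build="):
            build = line.split("=", 1)[1]
            continue
        if line.startswith("#") or line.startswith("name\t"):
            continue
        name, chrom, start, end, state, min_ov = line.split("\t")
        regions.append(
            SyndromeRegion(
                name=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                expected_state=state,
                min_overlap=float(min_ov),
                genome_build=build,
            )
        )
    return regions


def match_syndromes(
    segments: list[CNVSegment],
    catalog: Sequence[SyndromeRegion],
    build: str = "GRCh37",
) -> list[CNVSegment]:
    """Annotate segments in place with their best-matching syndrome region.

    A match requires state agreement and overlap of at least the region's
    ``min_overlap`` fraction of the *region* length; the largest overlap
    wins.  Matched segments are classified pathogenic.
    """
    for region in catalog:
        if region.genome_build != build:
            raise ValueError(
                f"catalog build {region.genome_build} does not match segment build {build}"
            )
    for seg in segments:
        best: Optional[SyndromeRegion] = None
        best_frac = 0.0
        for region in catalog:
            if region.chrom != seg.chrom or region.expected_state != seg.state:
                continue
            ov = min(seg.end, region.end) - max(seg.start, region.start)
            frac = max(ov, 0) / (region.end - region.start)
            if frac >= region.min_overlap and frac > best_frac:
                best, best_frac = region, frac
        if best is not None:
            seg.syndrome = best.name
            seg.syndrome_overlap = round(best_frac, 4)
            seg.classification = "pathogenic_match"
    return segments


# ---------------------------------------------------------------------------
# Per-sample screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Full screening report for one sample."""

    sample_id: str
    status: str  # "ok" | "no-call"
    ff: Optional[FFEstimate]
    aneuploidy: Optional["AneuploidyResult"]
    segments: list[CNVSegment]
    risk_labels: list[str]
    version: str = ""
    config_hash: str = ""


def screen_sample(
    sample: CorrectedCounts,
    stats: BatchStats,
    windows: WindowMap,
    catalog: Sequence[SyndromeRegion],
    sample_index: Optional[int] = None,
    hmm: Optional[HMMParams] = None,
    min_abs_seg_z: float = 3.0,
    ff: Optional[FFEstimate] = None,
    aneuploidy: Optional["AneuploidyResult"] = None,
    force: bool = False,
) -> ScreenResult:
    """Z-scores -> discretize -> Viterbi -> segments -> syndrome match."""
    if ff is not None and ff.qc_pass is False and not force:
        log.warning("sample %s: QC failed (%s); screening withheld", sample.sample_id, ",".join(ff.qc_reasons))
        return ScreenResult(
            sample_id=sample.sample_id,
            status="no-call",
            ff=ff,
            aneuploidy=None,
            segments=[],
            risk_labels=[],
        )
    hmm = hmm or HMMParams()
    z = z_scores(sample, stats, sample_index=sample_index)
    path = decode_states(z, windows, hmm)
    segs = segment(path, z, windows, min_abs_seg_z)
    segs = match_syndromes(segs, catalog, build=windows.genome_build)
    labels = [f"high risk: {s.syndrome}" for s in segs if s.classification == "pathogenic_match"]
    if aneuploidy is not None:
        labels += [f"aneuploidy: {chrom} {direction}" for chrom, direction in aneuploidy.calls]
    return ScreenResult(
        sample_id=sample.sample_id,
        status="ok",
        ff=ff,
        aneuploidy=aneuploidy,
        segments=segs,
        risk_labels=labels,
    )
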