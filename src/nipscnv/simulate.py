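"""Synthetic maternal-plasma cohort generator.

The generator produces per-window unique-read counts for a lot of plasma
samples with the generative structure the screening pipeline assumes:

* fetal fraction drawn from a truncated normal calibrated so the truncated
  distribution's mean/SD equal the configured cohort values (defaults are
  the observed pre-/post-enrichment cohort distributions: mean 9.44%,
  SD 4.03%, range [3.53%, 28.94%] before enrichment; mean 19.32%, SD 6.04%,
  range [7.57%, 35.54%] after);
* expected count per window lambda_w = depth * (expected_unique_w / total)
  * gcbias(gc_w) * dosage_w, with dosage 1 - ff/2 inside a fetal
  heterozygous deletion, 1 + ff/2 inside a duplication or on a trisomic
  chromosome, and 1 - ff/2 on chrX for a male fetus;
* Poisson count noise (unique reads at ~3,000 per Mb-window are
  near-Poisson; an overdispersion multiplier covers batch effects);
* chrY reads binomial in depth with success probability linear in fetal
  fraction for male fetuses.

Wet-lab enrichment is modeled purely as the shift between the two fetal
fraction distributions; fragment-length physics is deliberately not
simulated.  Ground truth per sample is returned for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

from .counts_io import SampleCounts, write_counts
from .fetal_fraction import FFBaselines
from .genome_windows import (
    MappabilityTrack,
    WindowMap,
    build_windows,
    uniform_track,
    write_window_map,
)

__all__ = [
    "FFDistribution",
    "PRE_ENRICHMENT",
    "POST_ENRICHMENT",
    "GCBias",
    "SimEvent",
    "SimConfig",
    "TruthTable",
    "truncnorm_parent_params",
    "sample_ff",
    "expected_profile",
    "simulate_sample",
    "simulate_cohort",
    "emit_sam_fixture",
    "default_genome_spec",
    "default_genome_windows",
    "synthetic_gc",
    "manual_window_map",
    "ws_case_map",
    "ws_cohort_map",
]

CHRY_NAMES = frozenset({"chrY", "Y"})


# ---------------------------------------------------------------------------
# Fetal-fraction model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FFDistribution:
    """Truncated-normal fetal-fraction model (fractions, not percent)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 1):
            raise ValueError("ff truncation range must satisfy 0 <= lo < hi <= 1")


PRE_ENRICHMENT = FFDistribution(mean=0.0944, sd=0.0403, lo=0.0353, hi=0.2894)
POST_ENRICHMENT = FFDistribution(mean=0.1932, sd=0.0604, lo=0.0757, hi=0.3554)


@lru_cache(maxsize=32)
def truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) such that N(mu, sigma) truncated to [lo, hi] has the
    requested mean and SD (moment matching).

    Using the target moments directly as parent parameters would bias the
    truncated mean (by ~0.3-0.6 percentage points for the default cohort
    models), so the two-equation system is solved numerically.
    """

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([float(m) - mean, math.sqrt(float(v)) - sd])

    sol = optimize.root(moments, x0=np.array([mean, math.log(sd)]), method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def sample_ff(rng: np.random.Generator, n: int, dist: FFDistribution) -> np.ndarray:
    """Draw n fetal fractions from the moment-matched truncated normal."""
    if dist.sd == 0:
        return np.full(n, dist.mean)
    mu, sigma = truncnorm_parent_params(dist.mean, dist.sd, dist.lo, dist.hi)
    a, b = (dist.lo - mu) / sigma, (dist.hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Events and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCBias:
    """Quadratic GC-bias curve 1 - strength*(gc - peak)^2, floored at 0.05."""

    peak: float = 0.40
    strength: float = 3.0

    def factor(self, gc: np.ndarray) -> np.ndarray:
        return np.maximum(1.0 - self.strength * (np.asarray(gc) - self.peak) ** 2, 0.05)


@dataclass(frozen=True)
class SimEvent:
    """A spiked fetal event; ``sample`` is a cohort index or "random"."""

    sample: int | str
    kind: str  # "het_del" | "het_dup" | "trisomy"
    chrom: str
    start: Optional[int] = None
    end: Optional[int] = None
    ff: Optional[float] = None      # override the drawn fetal fraction
    depth: Optional[float] = None   # override the drawn depth
    sex: Optional[str] = None       # override the drawn fetal sex

    def __post_init__(self) -> None:
        if self.kind not in ("het_del", "het_dup", "trisomy"):
            raise ValueError(f"unknown event kind {self.kind}")
        if self.kind != "trisomy" and (self.start is None or self.end is None):
            raise ValueError(f"{self.kind} event needs start and end")


@dataclass
class SimConfig:
    windows: WindowMap
    n_samples: int
    depth_mean: float = 10e6
    depth_sd: float = 0.5e6
    ff_model: FFDistribution = PRE_ENRICHMENT
    gc_bias: Optional[GCBias] = None
    events: Sequence[SimEvent] = field(default_factory=list)
    male_fraction: float = 0.5
    baselines: FFBaselines = field(default_factory=FFBaselines)
    overdispersion: float = 1.0  # variance multiplier; 1 = Poisson
    seed: int = 0
    batch_id: str = "sim"


@dataclass
class TruthTable:
    """Ground truth per simulated sample (one row each)."""

    table: pd.DataFrame

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-sample generation
# ---------------------------------------------------------------------------

def _overlap_fraction(windows: WindowMap, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-window fraction of the window covered by [start, end) on chrom."""
    frac = np.zeros(len(windows))
    sl = windows.chrom_slices().get(chrom)
    if sl is None:
        raise ValueError(f"event chromosome {chrom} not in window map")
    c_start, c_end = int(windows.start[sl][0]), int(windows.end[sl][-1])
    if start < c_start or end > c_end or end <= start:
        raise ValueError(f"event {chrom}:{start}-{end} outside genome bounds")
    ov = np.minimum(windows.end[sl], end) - np.maximum(windows.start[sl], start)
    frac[sl] = np.clip(ov / windows.lengths[sl], 0.0, 1.0) * (ov > 0)
    return frac


def dosage_profile(windows: WindowMap, ff: float, sex: str, events: Sequence[SimEvent]) -> np.ndarray:
    """Per-window dosage factor for one fetus."""
    dosage = np.ones(len(windows))
    for ev in events:
        if ev.kind == "trisomy":
            sl = windows.chrom_slices().get(ev.chrom)
            if sl is None:
                raise ValueError(f"event chromosome {ev.chrom} not in window map")
            dosage[sl] += ff / 2
        else:
            sign = -1.0 if ev.kind == "het_del" else 1.0
            dosage += sign * (ff / 2) * _overlap_fraction(windows, ev.chrom, ev.start, ev.end)
    if sex == "male":
        for name, sl in windows.chrom_slices().items():
            if name in ("chrX", "X"):
                dosage[sl] *= 1 - ff / 2
    return dosage


def expected_profile(
    windows: WindowMap,
    depth: float,
    ff: float,
    sex: str = "female",
    events: Sequence[SimEvent] = (),
    gc_bias: Optional[GCBias] = None,
) -> np.ndarray:
    """Expected count per window, lambda_w (chrY windows excluded: zero)."""
    eu = windows.expected_unique.astype(float).copy()
    is_y = np.isin(windows.chrom, list(CHRY_NAMES))
    eu[is_y] = 0.0
    total = eu.sum()
    if total <= 0:
        raise ValueError("window map has no unique-position mass")
    lam = depth * eu / total
    if gc_bias is not None:
        lam = lam * gc_bias.factor(windows.gc)
    lam = lam * dosage_profile(windows, ff, sex, events)
    return lam


def simulate_sample(
    windows: WindowMap,
    depth: float,
    ff: float,
    sex: str,
    events: Sequence[SimEvent],
    rng: np.random.Generator,
    gc_bias: Optional[GCBias] = None,
    baselines: FFBaselines = FFBaselines(),
    overdispersion: float = 1.0,
    sample_id: str = "sample",
    batch_id: str = "sim",
) -> tuple[SampleCounts, dict]:
    """One sample's counts plus its truth row."""
    lam = expected_profile(windows, depth, ff, sex, events, gc_bias)
    if overdispersion > 1.0:
        # Gamma-Poisson mixture with variance = overdispersion * lambda
        shape = lam / (overdispersion - 1.0)
        lam = rng.gamma(np.maximum(shape, 1e-12), overdispersion - 1.0)
    counts = rng.poisson(lam)

    p_y = baselines.b_female + (ff * (baselines.b_male_adult - baselines.b_female) if sex == "male" else 0.0)
    chry = int(rng.binomial(int(round(depth)), p_y))
    is_y = np.isin(windows.chrom, list(CHRY_NAMES))
    if np.any(is_y):
        eu_y = windows.expected_unique[is_y].astype(float)
        if eu_y.sum() > 0:
            counts[is_y] = rng.multinomial(chry, eu_y / eu_y.sum())
        total = int(counts.sum())
    else:
        total = int(counts.sum()) + chry

    sample = SampleCounts(
        sample_id=sample_id,
        raw=counts,
        total_unique_reads=total,
        chry_reads=chry,
        batch_id=batch_id,
    )
    truth = {
        "sample_id": sample_id,
        "ff": ff,
        "sex": sex,
        "depth": float(depth),
        "total_reads_drawn": total,
        "events": ";".join(
            f"{e.kind}:{e.chrom}" + (f":{e.start}-{e.end}" if e.start is not None else "")
            for e in events
        ),
    }
    return sample, truth


def simulate_cohort(config: SimConfig, out_dir: Optional[Path | str] = None) -> tuple[list[SampleCounts], TruthTable]:
    """Independent samples with events assigned as configured.

    With ``out_dir`` given, writes counts.tsv, truth.tsv, and windows.tsv.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    ffs = sample_ff(rng, n, config.ff_model)
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")
    depths = np.maximum(rng.normal(config.depth_mean, config.depth_sd, size=n), 1e5)

    events_by_sample: dict[int, list[SimEvent]] = {i: [] for i in range(n)}
    for ev in config.events:
        idx = int(rng.integers(n)) if ev.sample == "random" else int(ev.sample)
        if not (0 <= idx < n):
            raise ValueError(f"event sample index {idx} out of range")
        events_by_sample[idx].append(ev)
        if ev.ff is not None:
            ffs[idx] = ev.ff
        if ev.depth is not None:
            depths[idx] = ev.depth
        if ev.sex is not None:
            sexes[idx] = ev.sex

    samples: list[SampleCounts] = []
    truth_rows: list[dict] = []
    for i in range(n):
        evs = events_by_sample[i]
        sex = str(sexes[i])
        s, t = simulate_sample(
            config.windows,
            depth=float(depths[i]),
            ff=float(ffs[i]),
            sex=sex,
            events=evs,
            rng=rng,
            gc_bias=config.gc_bias,
            baselines=config.baselines,
            overdispersion=config.overdispersion,
            sample_id=f"S{i:03d}",
            batch_id=config.batch_id,
        )
        samples.append(s)
        truth_rows.append(t)
    truth = TruthTable(pd.DataFrame(truth_rows))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(samples, config.windows, out / "counts.tsv")
        truth.write(out / "truth.tsv")
        write_window_map(config.windows, out / "windows.tsv")
    return samples, truth


# ---------------------------------------------------------------------------
# SAM fixtures for the counting path
# ---------------------------------------------------------------------------

def emit_sam_fixture(
    windows: WindowMap,
    n_reads: int,
    rng: np.random.Generator,
    dup_frac: float = 0.1,
    unmapped_frac: float = 0.0,
    lowmapq_frac: float = 0.0,
    read_len: int = 50,
) -> str:
    """Tiny single-end SAM text whose per-window kept-read totals are exact.

    Kept reads are drawn per the window unique-mass shares; duplicate,
    unmapped, and low-MAPQ records are appended on top so the filter path is
    exercised.  The intended per-window totals are embedded in @CO lines.
    Only small synthetic genomes are accepted (fixture guard).
    """
    genome_size = int(windows.lengths.sum())
    if genome_size > 5_000_000:
        raise ValueError("fixture genome too large (> 5 Mb); use simulate_cohort for big runs")

    eu = windows.expected_unique.astype(float)
    if eu.sum() <= 0:
        raise ValueError("window map has no unique-position mass")
    per_window = rng.multinomial(n_reads, eu / eu.sum())

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    chrom_len: dict[str, int] = {}
    for name, sl in windows.chrom_slices().items():
        chrom_len[name] = int(windows.end[sl][-1])
    for name, ln in chrom_len.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{ln}")
    lines.append("@CO\tnipscnv-fixture kept per-window counts: " + ",".join(map(str, per_window)))

    def record(qname: str, flag: int, rname: str, pos0: int, mapq: int) -> str:
        if flag & 0x4:
            return f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{'A' * read_len}\t{'I' * read_len}"
        return (
            f"{qname}\t{flag}\t{rname}\t{pos0 + 1}\t{mapq}\t{read_len}M\t*\t0\t0\t"
            f"{'A' * read_len}\t{'I' * read_len}\tNM:i:0"
        )

    qn = 0
    kept_records: list[tuple[str, int]] = []
    for w, k in enumerate(per_window):
        lo = int(windows.start[w])
        hi = max(int(windows.end[w]) - read_len, lo)
        for _ in range(int(k)):
            pos = int(rng.integers(lo, hi + 1))
            kept_records.append((str(windows.chrom[w]), pos))
    for rname, pos in kept_records:
        lines.append(record(f"r{qn:06d}", 0, rname, pos, 60))
        qn += 1
    for _ in range(int(round(n_reads * dup_frac))):
        rname, pos = kept_records[int(rng.integers(len(kept_records)))]
        lines.append(record(f"d{qn:06d}", 1024, rname, pos, 60))
        qn += 1
    for _ in range(int(round(n_reads * unmapped_frac))):
        lines.append(record(f"u{qn:06d}", 4, "*", 0, 0))
        qn += 1
    for _ in range(int(round(n_reads * lowmapq_frac))):
        rname, pos = kept_records[int(rng.integers(len(kept_records)))]
        lines.append(record(f"m{qn:06d}", 0, rname, pos, 0))
        qn += 1
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Synthetic genomes
# ---------------------------------------------------------------------------

def synthetic_gc(chrom: str, pos: int) -> float:
    """Smooth deterministic GC landscape with per-chromosome phase."""
    phase = (sum(ord(c) for c in chrom) % 17) / 17.0
    return 0.42 + 0.06 * math.sin(2 * math.pi * (pos / 1.31e8 + phase))


def default_genome_spec(include_chr21: bool = True) -> list[tuple[str, int]]:
    """Macro-chromosome genome of ~2.85 Gb uniquely mappable mass.

    Autosomes are collapsed into four macro-chromosomes plus a chr21-sized
    one (so trisomy-21-like events are expressible) and chrX; chrY reads are
    tracked as scalars rather than windows.
    """
    spec = [
        ("A1", 700_000_000),
        ("A2", 700_000_000),
        ("A3", 650_000_000),
        ("A4", 600_000_000),
    ]
    if include_chr21:
        spec.append(("chr21", 47_000_000))
    spec.append(("chrX", 155_000_000))
    return spec


def default_genome_windows(
    target_avg_len: int = 1_000_000,
    bin_size: int = 100_000,
    include_chr21: bool = True,
) -> WindowMap:
    track = uniform_track(default_genome_spec(include_chr21), bin_size=bin_size, gc=synthetic_gc)
    return build_windows(track, target_avg_len)


def manual_window_map(
    spec: Sequence[tuple[str, Sequence[int]]],
    gc: Callable[[str, int], float] = synthetic_gc,
    genome_build: str = "synthetic",
) -> WindowMap:
    """Window map built from explicit per-chromosome window lengths.

    Every window is fully mappable (expected_unique = length), so maps with
    deliberately placed window boundaries — e.g. a window tiling exactly a
    known syndrome region — can be constructed for studies.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, lengths in spec:
        pos = 0
        for ln in lengths:
            if ln <= 0:
                raise ValueError("window lengths must be positive")
            chroms.append(name)
            starts.append(pos)
            ends.append(pos + int(ln))
            pos += int(ln)
    start_arr = np.array(starts, dtype=np.int64)
    end_arr = np.array(ends, dtype=np.int64)
    chrom_arr = np.array(chroms, dtype=object)
    mids = (start_arr + end_arr) // 2
    gc_arr = np.array([gc(c, int(m)) for c, m in zip(chrom_arr, mids)])
    return WindowMap(
        chrom=chrom_arr,
        start=start_arr,
        end=end_arr,
        expected_unique=(end_arr - start_arr).astype(float),
        gc=gc_arr,
        genome_build=genome_build,
    )


WS_REGION_START = 72_600_000  # window-aligned anchor just upstream of the WBS critical region


def ws_case_map(deletion_size_bp: int, macro_window: int = 10_000_000) -> WindowMap:
    """GRCh37-like map whose chr7 contains one window of exactly the deletion size.

    chr7 is tiled at 1.1 Mb with a single window spanning
    [72.6 Mb, 72.6 Mb + size); three 900 Mb macro-chromosomes bring the
    total uniquely mappable mass to ~2.86 Gb so per-window depth matches a
    ~10 M unique-read whole-genome run.
    """
    pre = [1_100_000] * 66  # [0, 72.6 Mb)
    post = [1_100_000] * 77
    chr7 = pre + [int(deletion_size_bp)] + post
    macro = [macro_window] * 90
    return manual_window_map(
        [("A1", macro), ("A2", macro), ("A3", macro), ("chr7", chr7)],
        genome_build="GRCh37",
    )


def ws_cohort_map(macro_window: int = 10_000_000) -> WindowMap:
    """Shared cohort map for the two reported-case deletion sizes.

    The 7q11.23 region is tiled by a 1.65 Mb window at [72.6, 74.25) Mb and
    a 0.11 Mb window at [74.25, 74.36) Mb: a 1.65 Mb deletion spans the
    first window exactly and a 1.76 Mb deletion spans both.
    """
    pre = [1_100_000] * 66
    post = [1_100_000] * 77
    chr7 = pre + [1_650_000, 110_000] + post
    macro = [macro_window] * 90
    return manual_window_map(
        [("A1", macro), ("A2", macro), ("A3", macro), ("chr7", chr7)],
        genome_build="GRCh37",
    )
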