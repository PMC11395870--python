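"""Pipeline orchestration, configuration, clinical-style reporting.

Ties the modules into the screening pipeline a lab would run per lot:

    counts -> GC correction -> total normalization -> lot statistics
    -> fetal fraction + QC -> aneuploidy Z -> window Z -> HMM -> segments
    -> syndrome matching -> per-sample reports

Report coordinates follow the microarray (ISCN-like) convention: 1-based
inclusive with an underscore separator, e.g.
``arr[GRCh37] 7q11.23(72,669,481_74,154,209)x1`` — copy number 1 for a
heterozygous loss, 3 for a gain.  Internal coordinates stay 0-based
half-open and are converted at this boundary only.

The module also hosts the worked-study drivers (simulated cohorts at the
reported case parameters) used by the acceptance script and tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .aneuploidy import AneuploidyResult, batch_aneuploidy_z, chromosome_representation
from .cnv_hmm import (
    BatchStats,
    CNVSegment,
    HMMParams,
    ScreenResult,
    SyndromeRegion,
    batch_stats,
    load_catalog,
    match_syndromes,
    normalize_totals,
    screen_sample,
    segment,
    z_scores,
)
from .counts_io import FilterParams, SampleCounts, count_sample, read_counts
from .fetal_fraction import FFBaselines, FFEstimate, QCThresholds, estimate_ff_chry, qc_sample
from .gc_correct import CorrectedCounts, correct_sample, identity_correction
from .genome_windows import WindowMap, read_window_map
from . import simulate as sim

log = logging.getLogger("nipscnv")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "format_iscn",
    "parse_iscn",
    "iscn_size_mb",
    "load_cytobands",
    "cohort_ff_summary",
    "screen_cohort",
    "result_to_dict",
    "result_from_dict",
    "ff_recovery_study",
    "ws_case_called_size",
    "ws_cohort_study",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed)."""

    windows: str
    out_dir: str
    counts: Optional[str] = None
    sams: list[str] = field(default_factory=list)
    catalog: Optional[str] = None
    batch_id: str = "batch"
    seed: int = 0
    force: bool = False
    min_batch: int = 8
    z_threshold: float = 3.0
    min_abs_seg_z: float = 3.0
    gc_enabled: bool = True
    gc_bin_width: float = 0.01
    filter: FilterParams = field(default_factory=FilterParams)
    baselines: FFBaselines = field(default_factory=FFBaselines)
    qc: QCThresholds = field(default_factory=QCThresholds)
    hmm: HMMParams = field(default_factory=HMMParams)
    call_chroms: Optional[list[str]] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Optional[Path] = None) -> "RunConfig":
        def respath(p):
            if p is None:
                return None
            p = Path(p)
            return str(p if p.is_absolute() or base is None else base / p)

        known = {
            "windows", "out_dir", "counts", "sams", "catalog", "batch_id", "seed",
            "force", "min_batch", "z_threshold", "min_abs_seg_z", "gc", "filter",
            "baselines", "qc", "hmm", "call_chroms",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "windows" not in raw or "out_dir" not in raw:
            raise ValueError("config must set 'windows' and 'out_dir'")
        gc = raw.get("gc", {})
        cfg = cls(
            windows=respath(raw["windows"]),
            out_dir=respath(raw["out_dir"]),
            counts=respath(raw.get("counts")),
            sams=[respath(p) for p in raw.get("sams", [])],
            catalog=respath(raw.get("catalog")),
            batch_id=str(raw.get("batch_id", "batch")),
            seed=int(raw.get("seed", 0)),
            force=bool(raw.get("force", False)),
            min_batch=int(raw.get("min_batch", 8)),
            z_threshold=float(raw.get("z_threshold", 3.0)),
            min_abs_seg_z=float(raw.get("min_abs_seg_z", 3.0)),
            gc_enabled=bool(gc.get("enabled", True)),
            gc_bin_width=float(gc.get("bin_width", 0.01)),
            filter=FilterParams(**raw.get("filter", {})),
            baselines=FFBaselines(**raw.get("baselines", {})),
            qc=QCThresholds(**raw.get("qc", {})),
            hmm=HMMParams(**raw.get("hmm", {})) if raw.get("hmm") else HMMParams(),
            call_chroms=raw.get("call_chroms"),
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        missing = []
        for label, p in [("windows", self.windows), ("counts", self.counts), ("catalog", self.catalog)] + [
            ("sam", s) for s in self.sams
        ]:
            if p is not None and not Path(p).exists():
                missing.append(f"{label}: {p}")
        if missing:
            raise FileNotFoundError("missing input paths: " + "; ".join(missing))
        if self.counts is None and not self.sams:
            raise ValueError("config must supply either 'counts' or 'sams'")

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        d["hmm"] = {
            "cuts": list(self.hmm.cuts),
            "emission": self.hmm.emission.tolist(),
            "transition": self.hmm.transition.tolist(),
            "initial": self.hmm.initial.tolist(),
        }
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.effective(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# ISCN-style formatting
# ---------------------------------------------------------------------------

def load_cytobands(path=None) -> pd.DataFrame:
    """Cytoband table (chrom, start, end, band), 0-based half-open.

    The packaged table is abridged to the bands the report format needs;
    positions without a band fall back to the chr:start_end form.
    """
    if path is None:
        ref = resources.files("nipscnv").joinpath("data/cytobands_grch37.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def _band_for(segment: CNVSegment, cytobands: pd.DataFrame) -> Optional[str]:
    rows = cytobands[cytobands["chrom"] == segment.chrom]
    if rows.empty:
        return None
    ov = np.minimum(rows["end"], segment.end) - np.maximum(rows["start"], segment.start)
    if ov.max() <= 0:
        return None
    row = rows.iloc[int(np.argmax(ov.values))]
    return f"{str(segment.chrom).removeprefix('chr')}{row['band']}"


def format_iscn(
    segment: CNVSegment,
    build: str = "GRCh37",
    cytobands: Optional[pd.DataFrame] = None,
) -> str:
    """Microarray-style coordinate string for a called segment.

    1-based inclusive coordinates with thousands separators; copy number 1
    for a loss, 3 for a gain.  Without a cytoband hit the region is written
    as chr:start_end.
    """
    start1 = segment.start + 1
    end1 = segment.end  # half-open end == inclusive end in 1-based
    copy = 1 if segment.state == "loss" else 3
    coords = f"{start1:,}_{end1:,}"
    band = _band_for(segment, cytobands) if cytobands is not None else None
    if band:
        return f"arr[{build}] {band}({coords})x{copy}"
    return f"arr[{build}] {segment.chrom}:{coords}x{copy}"


_ISCN_RE = re.compile(
    r"arr\[(?P<build>[^\]]+)\]\s*(?P<region>[^\s(]+)?\s*\(?(?P<start>[\d,]+)_(?P<end>[\d,]+)\)?x(?P<copy>\d+)"
)


def parse_iscn(text: str) -> dict:
    """Parse an ISCN-like string into build, region label, 1-based coords, copy."""
    m = _ISCN_RE.search(text.replace("chr", "chr").strip())
    if not m:
        raise ValueError(f"cannot parse ISCN string: {text!r}")
    return {
        "build": m.group("build"),
        "region": (m.group("region") or "").rstrip("(").rstrip(":"),
        "start": int(m.group("start").replace(",", "")),
        "end": int(m.group("end").replace(",", "")),
        "copy": int(m.group("copy")),
    }


def iscn_size_mb(text: str) -> float:
    """Fragment size in Mb (2 dp) implied by an ISCN coordinate string."""
    p = parse_iscn(text)
    return round((p["end"] - p["start"] + 1) / 1e6, 2)


# ---------------------------------------------------------------------------
# Cohort fetal-fraction summary
# ---------------------------------------------------------------------------

def cohort_ff_summary(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[pd.DataFrame, float, float]:
    """Percentile/mean/SD table for two FF cohorts plus a Welch t-test.

    Percentiles use linear interpolation between order statistics.  Returns
    (table, t, p) with the two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    qs = [1, 25, 50, 75, 99]
    rows = []
    for name, g in (("group_a", a), ("group_b", b)):
        pct = np.percentile(g, qs)
        rows.append(
            {"group": name, **{f"p{q}": v for q, v in zip(qs, pct)}, "mean": g.mean(), "sd": g.std(ddof=1), "n": len(g)}
        )
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return pd.DataFrame(rows), float(t), float(p)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def result_to_dict(res: ScreenResult) -> dict:
    return {
        "sample_id": res.sample_id,
        "status": res.status,
        "ff": None
        if res.ff is None
        else {
            "ff": res.ff.ff,
            "method": res.ff.method,
            "qc_pass": res.ff.qc_pass,
            "qc_reasons": list(res.ff.qc_reasons),
        },
        "aneuploidy": None
        if res.aneuploidy is None
        else {
            "chroms": list(res.aneuploidy.chroms),
            "z": [None if not np.isfinite(v) else float(v) for v in res.aneuploidy.z],
            "calls": [list(c) for c in res.aneuploidy.calls],
            "z_threshold": res.aneuploidy.z_threshold,
            "no_call": res.aneuploidy.no_call,
            "untestable": list(res.aneuploidy.untestable),
        },
        "segments": [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "state": s.state,
                "n_windows": s.n_windows,
                "mean_z": s.mean_z,
                "size_mb": s.size_mb,
                "syndrome": s.syndrome,
                "syndrome_overlap": s.syndrome_overlap,
                "classification": s.classification,
            }
            for s in res.segments
        ],
        "risk_labels": list(res.risk_labels),
        "version": res.version,
        "config_hash": res.config_hash,
    }


def result_from_dict(d: dict) -> ScreenResult:
    ff = None
    if d.get("ff") is not None:
        f = d["ff"]
        ff = FFEstimate(
            sample_id=d["sample_id"],
            ff=f["ff"],
            method=f["method"],
            qc_pass=f["qc_pass"],
            qc_reasons=list(f["qc_reasons"]),
        )
    an = None
    if d.get("aneuploidy") is not None:
        a = d["aneuploidy"]
        an = AneuploidyResult(
            sample_id=d["sample_id"],
            chroms=list(a["chroms"]),
            z=np.array([np.nan if v is None else v for v in a["z"]]),
            calls=[tuple(c) for c in a["calls"]],
            z_threshold=a["z_threshold"],
            no_call=a["no_call"],
            untestable=list(a["untestable"]),
        )
    segs = [
        CNVSegment(
            chrom=s["chrom"],
            start=s["start"],
            end=s["end"],
            state=s["state"],
            n_windows=s["n_windows"],
            mean_z=s["mean_z"],
            syndrome=s["syndrome"],
            syndrome_overlap=s["syndrome_overlap"],
            classification=s["classification"],
        )
        for s in d["segments"]
    ]
    return ScreenResult(
        sample_id=d["sample_id"],
        status=d["status"],
        ff=ff,
        aneuploidy=an,
        segments=segs,
        risk_labels=list(d["risk_labels"]),
        version=d.get("version", ""),
        config_hash=d.get("config_hash", ""),
    )


# ---------------------------------------------------------------------------
# Cohort screening driver
# ---------------------------------------------------------------------------

def screen_cohort(
    samples: Sequence[SampleCounts],
    windows: WindowMap,
    catalog: Sequence[SyndromeRegion],
    gc_enabled: bool = True,
    gc_bin_width: float = 0.01,
    baselines: FFBaselines = FFBaselines(),
    qc: QCThresholds = QCThresholds(),
    hmm: Optional[HMMParams] = None,
    z_threshold: float = 3.0,
    min_abs_seg_z: float = 3.0,
    min_batch: int = 8,
    call_chroms: Optional[Sequence[str]] = None,
    force: bool = False,
    batch_id: str = "batch",
) -> list[ScreenResult]:
    """Run the full per-lot screening pipeline in memory."""
    hmm = hmm or HMMParams()
    if gc_enabled:
        corrected = [correct_sample(s, windows, gc_bin_width) for s in samples]
    else:
        corrected = [identity_correction(s, windows) for s in samples]
    corrected = normalize_totals(corrected)
    stats = batch_stats(corrected, windows, min_samples=min_batch, force=force, batch_id=batch_id)

    ffs = [qc_sample(s, estimate_ff_chry(s, baselines, qc.min_ff), qc) for s in samples]

    default_autosomes = [c for c in windows.chromosomes() if c not in ("chrX", "X", "chrY", "Y")]
    reps = [chromosome_representation(c, windows) for c in corrected]
    aneu = batch_aneuploidy_z(
        reps,
        ff_estimates=ffs,
        z_threshold=z_threshold,
        min_ff=qc.min_ff,
        call_chroms=call_chroms if call_chroms is not None else default_autosomes,
        min_batch=min_batch,
        force=force,
    )

    results = []
    for i, sample in enumerate(corrected):
        res = screen_sample(
            sample,
            stats,
            windows,
            catalog,
            sample_index=i,
            hmm=hmm,
            min_abs_seg_z=min_abs_seg_z,
            ff=ffs[i],
            aneuploidy=aneu[i],
            force=force,
        )
        res.version = __version__
        results.append(res)
    return results


def run_pipeline(config: RunConfig) -> list[ScreenResult]:
    """File-based pipeline entry point: read inputs, screen, write reports.

    Writes per-sample JSON, a cohort TSV, called segments as BED5, and a log
    echoing every effective parameter once.  Deterministic given config,
    inputs, and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "samples").mkdir(exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("effective config: %s", json.dumps(config.effective(), sort_keys=True, default=str))
        windows = read_window_map(config.windows)
        catalog = load_catalog(config.catalog)
        if config.counts:
            samples = read_counts(config.counts, windows)
        else:
            samples = [
                count_sample(p, windows, config.filter, sample_id=Path(p).stem, batch_id=config.batch_id)
                for p in config.sams
            ]
        if len(samples) < config.min_batch and not config.force:
            raise ValueError(f"lot has {len(samples)} samples; need >= {config.min_batch} (or force)")

        results = screen_cohort(
            samples,
            windows,
            catalog,
            gc_enabled=config.gc_enabled,
            gc_bin_width=config.gc_bin_width,
            baselines=config.baselines,
            qc=config.qc,
            hmm=config.hmm,
            z_threshold=config.z_threshold,
            min_abs_seg_z=config.min_abs_seg_z,
            min_batch=config.min_batch,
            call_chroms=config.call_chroms,
            force=config.force,
            batch_id=config.batch_id,
        )
        chash = config.config_hash()
        cytobands = load_cytobands()
        rows = []
        bed_lines = []
        for res in results:
            res.config_hash = chash
            with open(out / "samples" / f"{res.sample_id}.json", "w") as jf:
                json.dump(result_to_dict(res), jf, indent=1, sort_keys=True)
            ff_val = "" if res.ff is None or res.ff.ff is None else f"{res.ff.ff:.4f}"
            an_calls = "" if res.aneuploidy is None else ";".join(f"{c}:{d}" for c, d in res.aneuploidy.calls)
            seg_desc = ";".join(format_iscn(s, windows.genome_build, cytobands) for s in res.segments)
            rows.append(
                "\t".join(
                    [
                        res.sample_id,
                        res.status,
                        ff_val,
                        "pass" if (res.ff and res.ff.qc_pass) else ",".join(res.ff.qc_reasons) if res.ff else "",
                        an_calls,
                        seg_desc,
                        ";".join(res.risk_labels),
                    ]
                )
            )
            for s in res.segments:
                bed_lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{abs(s.mean_z):.2f}\t{res.sample_id}")
        header = "sample_id\tstatus\tff\tqc\taneuploidy_calls\tsegments\trisk_labels"
        (out / "cohort.tsv").write_text(header + "\n" + "\n".join(rows) + "\n")
        (out / "segments.bed").write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
        return results
    finally:
        log.removeHandler(fh)
        fh.close()


# ---------------------------------------------------------------------------
# Worked studies at the reported case parameters
# ---------------------------------------------------------------------------

CASE1 = {"size_bp": 1_760_000, "ff": 0.1500, "depth": 9.95e6}
CASE2 = {"size_bp": 1_650_000, "ff": 0.1770, "depth": 5.81e6}


def ff_recovery_study(
    dist: sim.FFDistribution,
    n_samples: int = 1000,
    depth: float = 5e6,
    baselines: FFBaselines = FFBaselines(),
    seed: int = 0,
) -> float:
    """Cohort mean of chrY fetal-fraction estimates on simulated male-fetus
    samples, as a fraction.  Parameter-recovery check for the FF model."""
    rng = np.random.default_rng([seed, 101])
    ffs = sim.sample_ff(rng, n_samples, dist)
    p = baselines.b_female + ffs * (baselines.b_male_adult - baselines.b_female)
    chry = rng.binomial(int(depth), p)
    estimates = []
    for i in range(n_samples):
        counts = SampleCounts(
            sample_id=f"S{i}", raw=np.zeros(0, dtype=np.int64), total_unique_reads=int(depth), chry_reads=int(chry[i])
        )
        est = estimate_ff_chry(counts, baselines)
        estimates.append(est.ff if est.ff is not None else 0.0)
    return float(np.mean(estimates))


def _ws_batch_screen(
    windows: WindowMap,
    case_event: sim.SimEvent,
    n_samples: int,
    seed: int,
    mate_depth: float = 10e6,
) -> list[ScreenResult]:
    cfg = sim.SimConfig(
        windows=windows,
        n_samples=n_samples,
        depth_mean=mate_depth,
        depth_sd=0.0,
        ff_model=sim.POST_ENRICHMENT,
        events=[case_event],
        male_fraction=0.5,
        seed=seed,
        batch_id="ws-study",
    )
    samples, _truth = sim.simulate_cohort(cfg)
    return screen_cohort(
        samples,
        windows,
        load_catalog(),
        gc_enabled=True,
        batch_id="ws-study",
    )


def ws_case_called_size(
    size_bp: int,
    ff: float,
    depth: float,
    seed: int,
    n_samples: int = 30,
    n_replicates: int = 5,
) -> float:
    """Median called-deletion size (Mb) for a simulated case-like sample.

    Builds a GRCh37-like window map in which chr7 carries a window of
    exactly ``size_bp`` at the 7q11.23 anchor, spikes a heterozygous fetal
    deletion of that window into one sample of an ``n_samples`` lot (lot
    mates at the lab-typical ~10 M unique reads), screens the lot, and
    measures the loss segment overlapping the spiked region.  The median
    over seeded replicates is reported; a replicate with no overlapping
    loss call contributes 0.
    """
    windows = sim.ws_case_map(size_bp)
    start = sim.WS_REGION_START
    end = start + size_bp
    sizes = []
    for r in range(n_replicates):
        ev = sim.SimEvent(sample=0, kind="het_del", chrom="chr7", start=start, end=end, ff=ff, depth=depth, sex="male")
        results = _ws_batch_screen(windows, ev, n_samples, seed=int((seed + 7919 * r) % 2**31))
        case = results[0]
        called = 0.0
        for s in case.segments:
            if s.chrom == "chr7" and s.state == "loss" and min(s.end, end) - max(s.start, start) > 0:
                called = s.size_mb
                break
        sizes.append(called)
    return float(np.median(sizes))


def ws_cohort_study(seed: int, n_samples: int = 50) -> tuple[list[ScreenResult], list[str]]:
    """Cohort screen with the two reported WS cases spiked at their parameters.

    50 post-enrichment samples; sample 10 carries a 1.76 Mb and sample 30 a
    1.65 Mb heterozygous 7q11.23 deletion at the reported fetal fractions
    and unique-read totals.  Returns all screen results plus the IDs of
    samples flagged high-risk for the 7q11.23 syndrome.
    """
    windows = sim.ws_cohort_map()
    start = sim.WS_REGION_START
    events = [
        sim.SimEvent(sample=10, kind="het_del", chrom="chr7", start=start, end=start + CASE1["size_bp"],
                     ff=CASE1["ff"], depth=CASE1["depth"], sex="male"),
        sim.SimEvent(sample=30, kind="het_del", chrom="chr7", start=start, end=start + CASE2["size_bp"],
                     ff=CASE2["ff"], depth=CASE2["depth"], sex="male"),
    ]
    cfg = sim.SimConfig(
        windows=windows,
        n_samples=n_samples,
        depth_mean=10e6,
        depth_sd=0.5e6,
        ff_model=sim.POST_ENRICHMENT,
        events=events,
        seed=int(seed % 2**31),
        batch_id="ws-cohort",
    )
    samples, _truth = sim.simulate_cohort(cfg)
    results = screen_cohort(samples, windows, load_catalog(), gc_enabled=True, batch_id="ws-cohort")
    positives = [
        r.sample_id
        for r in results
        if any(s.classification == "pathogenic_match" and s.chrom == "chr7" for s in r.segments)
    ]
    return results, positives
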