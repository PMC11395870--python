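"""GC-bias correction of per-window read counts.

PCR amplification during library preparation under-represents fragments from
GC-poor and GC-rich windows.  The dependence of expected count on window GC
is estimated per sample — PCR bias varies by library — by grouping usable
windows into narrow GC bins, taking the median count per bin (robust to
CNV-carrying windows), and fitting a cubic smoothing spline through the bin
medians (smoothing parameter by generalized cross-validation; a fixed-knot
cubic interpolant is the fallback when the GCV fit is unavailable).  The
corrected read number is

    CRN_w = raw_w * reference / m(gc_w)

where ``m`` is the fitted curve and the reference level is the median over
usable windows, so correction rescales rather than inflates the sample.
Both the curve and the reference are fitted on per-unique-position *rates*
(count divided by the window's expected unique-position mass) rather than
raw counts: windows are built to constant expected mass, but rates keep the
fit meaningful when masses vary (synthetic maps mixing coarse and fine
windows, remainder windows), because the correction factor is a ratio of
rates and is invariant to window mass.  GC values are clipped to the
sample's [1st, 99th] GC percentile before evaluation; the spline is never
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import interpolate

from .counts_io import SampleCounts
from .genome_windows import WindowMap

__all__ = ["GCModel", "CorrectedCounts", "fit_gc_model", "apply_gc_correction"]

DEFAULT_BIN_WIDTH = 0.01
MIN_USABLE_WINDOWS = 50
MIN_GC_BINS = 5


@dataclass
class GCModel:
    """Fitted expected-rate-vs-GC curve for one sample.

    ``spline`` and ``reference`` are on the per-unique-position rate scale;
    the correction factor reference/m(gc) is dimensionless.
    """

    spline: object  # callable gc -> expected rate
    reference: float
    clip: tuple[float, float]
    bin_gc: np.ndarray
    bin_median: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    method: str = "smoothing_spline"

    def expected(self, gc: np.ndarray) -> np.ndarray:
        """Evaluate m(gc) with clipping; floored at 1% of the reference."""
        g = np.clip(np.asarray(gc, dtype=float), self.clip[0], self.clip[1])
        m = np.asarray(self.spline(g), dtype=float)
        return np.maximum(m, 0.01 * self.reference)


@dataclass
class CorrectedCounts:
    """GC-corrected read numbers (CRN) per window; NaN where unusable."""

    sample_id: str
    crn: np.ndarray
    total_unique_reads: int = 0
    chry_reads: int = 0
    batch_id: str = ""
    model: Optional[GCModel] = None

    def __post_init__(self) -> None:
        self.crn = np.asarray(self.crn, dtype=np.float64)
        finite = np.isfinite(self.crn)
        if np.any(self.crn[finite] < 0):
            raise ValueError("CRN must be >= 0")

    @property
    def total(self) -> float:
        return float(np.nansum(self.crn))


def fit_gc_model(
    counts: SampleCounts | CorrectedCounts,
    windows: WindowMap,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> GCModel:
    values = counts.raw if isinstance(counts, SampleCounts) else counts.crn
    if len(values) != len(windows):
        raise ValueError("window count mismatch between sample and window map")
    usable = windows.usable & np.isfinite(np.asarray(values, dtype=float))
    if usable.sum() < MIN_USABLE_WINDOWS:
        raise ValueError(f"need >= {MIN_USABLE_WINDOWS} usable windows to fit a GC model")
    # per-unique-position rate: invariant to window mass
    v = np.asarray(values, dtype=float)[usable] / windows.expected_unique[usable]
    gc = windows.gc[usable]

    bin_idx = np.round(gc / bin_width).astype(int)
    uniq_bins = np.unique(bin_idx)
    if len(uniq_bins) < MIN_GC_BINS:
        raise ValueError("insufficient GC spread")
    centers = uniq_bins * bin_width
    medians = np.array([np.median(v[bin_idx == b]) for b in uniq_bins])

    method = "smoothing_spline"
    try:
        spline = interpolate.make_smoothing_spline(centers, medians)
    except Exception:
        spline = interpolate.CubicSpline(centers, medians)
        method = "cubic_interpolation"

    clip = (float(np.percentile(gc, 1)), float(np.percentile(gc, 99)))
    reference = float(np.median(v))
    return GCModel(
        spline=spline,
        reference=reference,
        clip=clip,
        bin_gc=centers,
        bin_median=medians,
        bin_width=bin_width,
        method=method,
    )


def apply_gc_correction(
    counts: SampleCounts | CorrectedCounts,
    model: GCModel,
    windows: WindowMap,
) -> CorrectedCounts:
    values = counts.raw if isinstance(counts, SampleCounts) else counts.crn
    if len(values) != len(windows):
        raise ValueError("window count mismatch between sample and window map")
    v = np.asarray(values, dtype=float)
    m = model.expected(windows.gc)
    crn = v * (model.reference / m)
    crn[~windows.usable] = np.nan
    crn[~np.isfinite(v)] = np.nan
    return CorrectedCounts(
        sample_id=counts.sample_id,
        crn=crn,
        total_unique_reads=getattr(counts, "total_unique_reads", 0),
        chry_reads=getattr(counts, "chry_reads", 0),
        batch_id=getattr(counts, "batch_id", ""),
        model=model,
    )


def correct_sample(counts: SampleCounts, windows: WindowMap, bin_width: float = DEFAULT_BIN_WIDTH) -> CorrectedCounts:
    """Fit and apply in one step (the per-sample pipeline path)."""
    return apply_gc_correction(counts, fit_gc_model(counts, windows, bin_width), windows)


def identity_correction(counts: SampleCounts, windows: WindowMap) -> CorrectedCounts:
    """Pass counts through unchanged (GC correction disabled in the config)."""
    crn = counts.raw.astype(float)
    crn = crn.copy()
    crn[~windows.usable] = np.nan
    return CorrectedCounts(
        sample_id=counts.sample_id,
        crn=crn,
        total_unique_reads=counts.total_unique_reads,
        chry_reads=counts.chry_reads,
        batch_id=counts.batch_id,
        model=None,
    )
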