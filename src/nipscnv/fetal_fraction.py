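"""Fetal-fraction estimation from chrY representation, and sample QC.

For a male fetus, the proportion of plasma reads mapping to chrY rises
linearly with the fetal fraction (ff): at ff = 0 only background mismapping
remains (``b_female``), at ff = 1 the sample would look like an adult male
genome (``b_male_adult``).  Inverting that line gives the estimator

    ff = (R_y - b_female) / (b_male_adult - b_female),  clamped to [0, 1],

with R_y = chrY_reads / total_unique_reads.  The two anchors are calibration
constants supplied by configuration; the packaged defaults suit the synthetic
genome and real deployments must calibrate them.  Samples whose R_y does not
exceed a male-fetus decision threshold are presumed to carry a female fetus;
their fetal fraction is not estimable by this method (the genome-wide
regression approach used for female fetuses is out of scope) and they skip
the minimum-ff QC gate with a logged caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .counts_io import SampleCounts

__all__ = ["FFBaselines", "FFEstimate", "QCThresholds", "estimate_ff_chry", "qc_sample"]

log = logging.getLogger("nipscnv")


@dataclass(frozen=True)
class FFBaselines:
    """chrY read-proportion anchors: ff = 0 (female background) and ff = 1."""

    b_female: float = 1e-4
    b_male_adult: float = 2.1e-3
    source: str = "default-synthetic"

    def __post_init__(self) -> None:
        if not (0 <= self.b_female < self.b_male_adult <= 1):
            raise ValueError("require 0 <= b_female < b_male_adult <= 1")


@dataclass(frozen=True)
class QCThresholds:
    min_ff: float = 0.035
    min_unique_reads: int = 5_000_000


@dataclass
class FFEstimate:
    sample_id: str
    ff: Optional[float]
    method: str  # "chrY" | "unavailable"
    qc_pass: Optional[bool] = None
    qc_reasons: list[str] = field(default_factory=list)


def estimate_ff_chry(
    counts: SampleCounts,
    baselines: FFBaselines = FFBaselines(),
    min_ff: float = 0.035,
) -> FFEstimate:
    """Linear two-anchor chrY estimator.

    The male-fetus decision threshold is a quarter of the chrY excess that a
    male fetus at the minimum reportable ff would produce; below it the
    sample is treated as carrying a female fetus (method "unavailable").
    """
    if counts.total_unique_reads <= 0:
        raise ValueError(f"sample {counts.sample_id}: zero total unique reads")
    span = baselines.b_male_adult - baselines.b_female
    r_y = counts.chry_reads / counts.total_unique_reads
    threshold = baselines.b_female + 0.25 * span * min_ff
    if r_y <= threshold:
        return FFEstimate(sample_id=counts.sample_id, ff=None, method="unavailable")
    ff = (r_y - baselines.b_female) / span
    ff = min(max(ff, 0.0), 1.0)
    return FFEstimate(sample_id=counts.sample_id, ff=ff, method="chrY")


def qc_sample(
    counts: SampleCounts,
    ff: FFEstimate,
    thresholds: QCThresholds = QCThresholds(),
) -> FFEstimate:
    """Populate the QC fields; callers refuse CNV/aneuploidy work on failures.

    A presumed-female sample (method "unavailable") cannot be gated on ff;
    it passes that gate with a logged caveat.
    """
    reasons: list[str] = []
    if ff.method == "chrY":
        if ff.ff is not None and ff.ff < thresholds.min_ff:
            reasons.append("low_ff")
    else:
        log.info(
            "sample %s: fetal fraction unavailable (presumed female fetus); min_ff gate skipped",
            counts.sample_id,
        )
    if counts.total_unique_reads < thresholds.min_unique_reads:
        reasons.append("low_depth")
    ff.qc_pass = not reasons
    ff.qc_reasons = reasons
    return ff
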