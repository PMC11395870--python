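# Methods

This note documents the statistical model, the defaults that matter, and
the design choices made where the design was genuinely open.

## Signal model

Plasma cfDNA from a pregnancy is a maternal/placental mixture with fetal
fraction *ff*. For a fetus heterozygous for a deletion, the expected read
depth over the deleted interval is scaled by 1 − *ff*/2; a duplication or a
trisomic chromosome scales by 1 + *ff*/2; a male fetus scales chrX by
1 − *ff*/2 and contributes chrY reads in proportion to *ff*. At the
coverage this screening operates at (~10 M unique reads genome-wide,
~3,000–3,500 reads per ~1 Mb window), per-window unique-read counts are
close to Poisson, so a heterozygous deletion of one window shifts its count
by roughly (*ff*/2)·√λ standard deviations — about 4–6 at *ff* 15–18% —
which is the entire detectability budget of the method.

## Windows

Windows are built per chromosome by accumulating fixed-size mappability
bins (default 10 kb synthetic, 100 kb for the packaged macro-genome) until
a quota of uniquely mappable positions is reached; the quota is the
chromosome total divided by `round(length / target_avg_len)`. Windows never
cross chromosomes; the last window absorbs the remainder; per-window GC is
the mappable-mass-weighted mean of bin GC. `target_avg_len` defaults to
1 Mb; events near the 1.5 Mb scale benefit from finer or deliberately
aligned windows, which `manual_window_map` supports. Coordinates are
0-based half-open internally and converted to 1-based inclusive only in
report strings.

## Unique-read filter

Mapped, primary, non-duplicate records with MAPQ ≥ 30 (uniqueness proxy —
multi-mappers receive MAPQ 0 from standard aligners) and NM ≤ 2 are
retained; a missing NM tag passes permissively and is logged once.
Paired-end input counts read 1 only. Reads on contigs without windows still
count toward the genome-wide total and the chrY tally, which fetal-fraction
estimation and QC need.

## GC correction

Each sample gets its own bias curve (PCR bias varies by library): usable
windows are grouped into GC bins of width 0.01, the median count *rate*
(count / expected unique positions) is taken per bin, and a cubic smoothing
spline (smoothing parameter by generalized cross-validation;
`scipy.interpolate.make_smoothing_spline`) is fitted through the bin
medians; a fixed-knot cubic interpolant is the fallback if the GCV fit is
unavailable. Rates rather than raw counts keep the fit meaningful when
window masses vary. Fitting requires ≥ 50 usable windows over ≥ 5 GC bins;
GC is clipped to the sample's [1st, 99th] percentile so the spline never
extrapolates, and the fitted curve is floored at 1% of the reference. The
correction CRN_w = raw_w · reference/m(gc_w) rescales rather than inflates:
on simulated samples the total is preserved within 5% and re-correcting a
corrected sample changes it by < 2% RMS.

## Lot statistics and window Z

Z_w = (CRN_w − CRN_mean,w)/SD_CRN,w with mean and (n−1)-denominator SD over
the samples of the same sequencing lot (minimum 8 unless forced). Three
robustness layers, all motivated by desk-scale lots:

* **Total normalization.** Each sample's CRN vector is scaled to the lot
  median total first; without it, a 5.8 M-read sample in a 10 M-read lot is
  globally depressed and every window looks deleted.
* **Leave-one-out.** A sample is excluded from its own reference mean/SD,
  so its signal cannot shrink the deviation being tested.
* **Iterative outlier trimming.** Samples with |z| > 3 at a window are
  removed from that window's statistics and the statistics recomputed until
  the kept set converges (≤ 5 rounds). One pass is not enough: when two lot
  mates carry the same event, removing the first outlier is what unmasks
  the second. Under the null the expected trimming rate is 0.27% per
  window, leaving the SD essentially unbiased.

Windows are unusable when SD is zero, fewer than three samples contribute,
or the index of dispersion (SD²/mean, ≈ 1 under Poisson for any window
mass) exceeds 10× the lot median.

## HMM segmentation

Z values are binned at cut points (−4, −2.5, 2.5, 4) into five symbols
(boundary values take the more extreme symbol; missing windows emit the
neutral symbol and are masked). A three-state discrete-emission HMM is
decoded per chromosome by Viterbi in log space with deterministic
tie-breaking preferring neutral, then loss, then gain.

Defaults: neutral self-transition 0.998 with 0.001 to each event state;
loss/gain self-transition 0.7 with 0.3 back to neutral; cross loss↔gain 0.
Neutral emissions are the standard-normal bin masses; loss emissions are
(0.45, 0.35, 0.18999, 0.01, 10⁻⁵) over (S--, S-, S0, S+, S++), gain
mirrored. Two of these choices deserve explanation:

* Event self-transition 0.7 (not higher): a stickier event state annexes
  neutral windows downstream of a strong single-window event, which both
  mis-sizes the call and dilutes the run's aggregate evidence. 0.7 still
  bridges one weak interior window of a real multi-window event, and it
  *increases* the net log-odds for flipping a lone S-- window (≈ +1.4).
* The opposite-extreme emission (S++ under loss, S-- under gain) is 10⁻⁵,
  *below* the neutral state's own far-tail mass (3.2 × 10⁻⁵). A window
  deviating 4 SD against an event's direction is physically better
  explained by euploidy; with symmetric 0.01 tails a gain run flanked by
  two noisy S+ windows can absorb a genuine deletion window.

With these defaults a single window at |z| ≥ 4 flips its state and a
single window at |z| in (2.5, 4] does not — deliberate: at the depths this
screen targets, a real event aligned to one window produces |z| ≥ 4.

## Segments, refinement, and the segment filter

Maximal non-neutral runs become candidate segments. Because the decoder
occasionally annexes a noisy neighbor or bridges two unrelated deviant
windows across neutral ones, each run is refined: split at interior windows
with signed z short of the weak cut (2.5), and flanks trimmed back to the
outermost window with signed z ≥ 3 (skipped when no window in the piece is
that strong, so a wide run of individually weak windows survives intact).
A surviving piece is reported when its Stouffer-combined Z (Σz/√n) reaches
3 in magnitude — for a single window this is exactly |z| ≥ 3; for longer
runs it aggregates evidence correctly instead of letting weak flanks veto a
strong window. Segment coordinates are window-aligned; sizes are reported
in Mb to 2 decimals.

## Syndrome catalog and matching

The packaged catalog (GRCh37) covers the Williams–Beuren 7q11.23 region
(chr7:72,700,000–74,100,000), 22q11.2, 15q11.2–q13, 5p15, and 1p36, each
with expected state *loss* and minimum overlap 0.5 of the region length.
A segment matches when states agree and the overlap fraction of the region
reaches the region's threshold; the largest overlap wins and the segment is
classified a pathogenic match ("high risk: <syndrome>"). Coordinates are
configuration data, not code. The packaged cytoband table is abridged to
the chromosome-7 bands around 7q11.23; report strings elsewhere fall back
to `chr:start_end` form.

## Aneuploidy Z-test

Per-chromosome representation = chromosome CRN sum / genome CRN sum over
usable windows (scale-invariant, so normalization is immaterial). The same
leave-one-out, outlier-trimmed lot statistics yield per-chromosome z; calls
at |z| ≥ 3 on the configured chromosomes (autosomes by default — sex
chromosomes are reported without karyotype interpretation). Samples whose
chrY-based ff is known and below the gate are no-calls, not negatives.
Under a euploid null with lots of 100, the empirical per-chromosome type-I
error at |z| ≥ 3 is ≈ 0.4% (t-tails with n ≈ 100), within the 1% bound the
tests assert.

## Fetal fraction and QC

ff = (R_y − b_female)/(b_male_adult − b_female), clamped to [0, 1], with
R_y the chrY read proportion and anchors b_female = 10⁻⁴ (female-fetus
background mismapping) and b_male_adult = 2.1 × 10⁻³ (fully male genome).
These defaults suit the synthetic genome; real deployments must calibrate
them. A sample is treated as male-fetus when R_y exceeds
b_female + 0.25·(b_male_adult − b_female)·min_ff; below that the method is
"unavailable" (the genome-wide regression used for female fetuses is out of
scope) and the ff QC gate is skipped with a logged caveat. QC thresholds:
min_ff 3.5% (the 1st percentile of the unenriched cohort), minimum 5 M
unique reads.

## Simulator

Expected count per window: λ_w = depth · (expected_unique_w / Σ) ·
gcbias(gc_w) · dosage_w; counts are Poisson (an optional Gamma–Poisson
overdispersion multiplier covers batch effects, default off — unique reads
at these depths are near-Poisson). chrY reads are Binomial(depth, b_female
+ ff·(b_male_adult − b_female)) for male fetuses. Fetal fractions are drawn
from a truncated normal whose *parent* parameters are solved numerically so
the truncated distribution's mean and SD equal the configured cohort values
(pre-enrichment 9.44% ± 4.03% on [3.53%, 28.94%]; post-enrichment 19.32% ±
6.04% on [7.57%, 35.54%]); using the target moments directly as parent
parameters would bias the truncated mean by 0.3–0.6 points. Enrichment is
modeled solely as the shift between the two distributions; fragment-length
physics is not simulated.

The default synthetic genome collapses the autosomes into four macro
chromosomes plus a chr21-sized autosome (so trisomy-21-like events are
expressible) and chrX, ~2.85 Gb of uniquely mappable mass — matching the
per-window depth regime of a real run; chrY is tracked as scalar read
counts rather than windows, since chrY windows are uninformative for female
fetuses. Study-scale maps (`ws_case_map`, `ws_cohort_map`) tile a chr7-like
chromosome at 1.1 Mb with deliberately placed windows of exactly the
reported deletion sizes at the 7q11.23 anchor, plus three 900 Mb macro
chromosomes to preserve total mass.

What the simulator does **not** emulate: maternal CNVs, confined placental
mosaicism, sequence-level errors, alignment artifacts, batch-correlated
bias beyond the optional overdispersion, and real mappability structure.
Passing tests therefore demonstrate the statistical machinery under the
stated generative model, not clinical performance on real plasma libraries.

## Problem sizes used in tests and the acceptance script

Simulated studies are scaled to run in seconds to minutes on one CPU while
preserving the per-window depth of the real setting: lots of 20–100
samples, maps of 100–800 windows, 200 replicates per point for sensitivity
curves, 1,000 samples for fetal-fraction recovery and the aneuploidy null.
The case-sizing studies screen a 30-sample lot with the case's reported
fetal fraction and unique-read total (lot mates at the lab-typical 10 M
reads) and report the median called size over five seeded replicates — a
single Viterbi decode of a one-window event succeeds with probability
~0.95, so the median is the stable measurement of the same quantity.

## Known limitations

* Breakpoints are window-aligned; there is no sub-window refinement, so a
  called size reflects the window grid (the NIPS-reported sizes of the two
  cases differ from their microarray-confirmed sizes for the same reason).
* Female-fetus fetal fraction is not estimated; such samples skip the ff
  gate and their screening sensitivity is consequently not guaranteed.
* The chrY anchors and the syndrome catalog ship with synthetic-genome and
  literature defaults respectively; both are configuration that a real
  deployment must calibrate/curate.
* Lots mixing very different depths are handled by total normalization,
  but a sample at half the lot depth still carries ~√2 more per-window
  noise, and its calls are correspondingly less reliable.
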