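"""Generative model: dosage arithmetic, FF calibration, determinism, LLN."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from nipscnv.fetal_fraction import FFBaselines
from nipscnv import simulate as sim


@pytest.fixture
def small_map(uniform_10mb_map):
    return uniform_10mb_map


class TestDosage:
    def test_het_del_scales_expected_count_by_one_minus_half_ff(self, small_map):
        ev = sim.SimEvent(sample=0, kind="het_del", chrom="chr1", start=5_000_000, end=7_000_000)
        lam0 = sim.expected_profile(small_map, 1e6, ff=0.2)
        lam = sim.expected_profile(small_map, 1e6, ff=0.2, events=[ev])
        ratio = lam / lam0
        assert np.allclose(ratio[5:7], 0.9)
        assert np.allclose(np.delete(ratio, [5, 6]), 1.0)

    def test_het_dup_and_partial_overlap(self, small_map):
        ev = sim.SimEvent(sample=0, kind="het_dup", chrom="chr1", start=5_500_000, end=6_000_000)
        ratio = sim.expected_profile(small_map, 1e6, 0.2, events=[ev]) / sim.expected_profile(small_map, 1e6, 0.2)
        assert ratio[5] == pytest.approx(1 + 0.1 * 0.5)  # half the window duplicated

    def test_trisomy_scales_whole_chromosome(self):
        wmap = sim.default_genome_windows(10_000_000)
        ev = sim.SimEvent(sample=0, kind="trisomy", chrom="chr21")
        ratio = sim.expected_profile(wmap, 1e7, 0.2, events=[ev]) / sim.expected_profile(wmap, 1e7, 0.2)
        on21 = wmap.chrom == "chr21"
        assert np.allclose(ratio[on21], 1.1)
        assert np.allclose(ratio[~on21], 1.0)

    def test_male_fetus_reduces_chrx_dosage(self):
        wmap = sim.default_genome_windows(10_000_000)
        lam_f = sim.expected_profile(wmap, 1e7, 0.2, sex="female")
        lam_m = sim.expected_profile(wmap, 1e7, 0.2, sex="male")
        onx = wmap.chrom == "chrX"
        assert np.allclose(lam_m[onx] / lam_f[onx], 0.9)
        assert np.allclose(lam_m[~onx], lam_f[~onx])

    def test_event_outside_genome_rejected(self, small_map):
        with pytest.raises(ValueError, match="outside genome"):
            sim.expected_profile(
                small_map, 1e6, 0.2,
                events=[sim.SimEvent(sample=0, kind="het_del", chrom="chr1", start=9_000_000, end=11_000_000)],
            )
        with pytest.raises(ValueError, match="not in window map"):
            sim.expected_profile(
                small_map, 1e6, 0.2,
                events=[sim.SimEvent(sample=0, kind="het_del", chrom="chr9", start=0, end=1_000_000)],
            )


class TestFFModel:
    @pytest.mark.parametrize("dist", [sim.PRE_ENRICHMENT, sim.POST_ENRICHMENT])
    def test_moment_matched_parent_reproduces_target(self, dist):
        mu, sigma = sim.truncnorm_parent_params(dist.mean, dist.sd, dist.lo, dist.hi)
        a, b = (dist.lo - mu) / sigma, (dist.hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert float(m) == pytest.approx(dist.mean, abs=1e-8)
        assert float(np.sqrt(v)) == pytest.approx(dist.sd, abs=1e-8)

    def test_draws_respect_truncation(self):
        rng = np.random.default_rng(0)
        ffs = sim.sample_ff(rng, 5000, sim.POST_ENRICHMENT)
        assert ffs.min() >= sim.POST_ENRICHMENT.lo
        assert ffs.max() <= sim.POST_ENRICHMENT.hi

    def test_cohort_ff_mean_matches_published_distribution(self, small_map):
        """50 post-enrichment samples land within 2 SE of the 19.32% mean."""
        cfg = sim.SimConfig(windows=small_map, n_samples=50, depth_mean=1e6, depth_sd=0.0,
                            ff_model=sim.POST_ENRICHMENT, seed=11)
        _, truth = sim.simulate_cohort(cfg)
        se = sim.POST_ENRICHMENT.sd / np.sqrt(50)
        assert abs(truth.table["ff"].mean() - 0.1932) < 2 * se


class TestCohort:
    def test_fixed_seed_is_bitwise_reproducible(self, small_map):
        cfg = sim.SimConfig(windows=small_map, n_samples=5, depth_mean=1e6, seed=42)
        a, ta = sim.simulate_cohort(cfg)
        b, tb = sim.simulate_cohort(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.raw, y.raw)
            assert x.chry_reads == y.chry_reads
        assert ta.table.equals(tb.table)

    def test_zero_samples_rejected(self, small_map):
        with pytest.raises(ValueError):
            sim.simulate_cohort(sim.SimConfig(windows=small_map, n_samples=0))

    def test_truth_table_has_one_row_per_sample(self, small_map):
        cfg = sim.SimConfig(windows=small_map, n_samples=7, depth_mean=1e6, seed=1)
        samples, truth = sim.simulate_cohort(cfg)
        assert len(truth.table) == 7
        assert list(truth.table["sample_id"]) == [s.sample_id for s in samples]

    def test_event_assignment_and_overrides(self, small_map):
        ev = sim.SimEvent(sample=2, kind="het_del", chrom="chr1", start=0, end=2_000_000,
                          ff=0.15, depth=2e6, sex="male")
        cfg = sim.SimConfig(windows=small_map, n_samples=4, depth_mean=1e6, depth_sd=0.0,
                            events=[ev], seed=3)
        _, truth = sim.simulate_cohort(cfg)
        row = truth.table.iloc[2]
        assert row["ff"] == 0.15
        assert row["sex"] == "male"
        assert row["depth"] == 2e6
        assert "het_del:chr1:0-2000000" in row["events"]

    def test_cohort_files_written(self, small_map, tmp_path):
        cfg = sim.SimConfig(windows=small_map, n_samples=3, depth_mean=1e6, seed=1)
        sim.simulate_cohort(cfg, out_dir=tmp_path)
        for name in ("counts.tsv", "truth.tsv", "windows.tsv"):
            assert (tmp_path / name).exists()

    def test_chry_reads_linear_in_ff_for_males(self, small_map):
        rng = np.random.default_rng(0)
        base = FFBaselines()
        ffs = (0.05, 0.25)
        props = []
        for ff in ffs:
            s, _ = sim.simulate_sample(small_map, 5e6, ff, "male", [], rng)
            props.append(s.chry_reads / 5e6)
        for ff, p in zip(ffs, props):
            expect = base.b_female + ff * (base.b_male_adult - base.b_female)
            assert p == pytest.approx(expect, rel=0.2)


def test_law_of_large_numbers_per_window():
    """Empirical mean count over 500 euploid samples tracks lambda within 3%."""
    wmap = sim.default_genome_windows(50_000_000)  # 58 coarse windows
    lam = sim.expected_profile(wmap, 2e6, ff=0.1)
    rng = np.random.default_rng(9)
    total = np.zeros(len(wmap))
    n = 500
    for _ in range(n):
        s, _ = sim.simulate_sample(wmap, 2e6, 0.1, "female", [], rng)
        total += s.raw
    assert np.all(np.abs(total / n / lam - 1) < 0.03)
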