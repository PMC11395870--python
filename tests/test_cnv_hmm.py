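"""Lot statistics, Z formula, HMM decoding vs brute force, segmentation,
syndrome matching, and screening composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nipscnv.cnv_hmm import (
    HMMParams,
    ZProfile,
    batch_stats,
    decode_states,
    discretize,
    load_catalog,
    match_syndromes,
    normalize_totals,
    screen_sample,
    segment,
    viterbi,
    z_scores,
    CNVSegment,
    SyndromeRegion,
)
from nipscnv.fetal_fraction import FFEstimate
from nipscnv.gc_correct import CorrectedCounts
from nipscnv.genome_windows import build_windows, uniform_track

from conftest import euploid_stats, path_logprob, viterbi_bruteforce


def crn(values, sid="s"):
    return CorrectedCounts(sid, np.asarray(values, dtype=float))


def stats_from(columns, **kw):
    """BatchStats from an (n_samples, n_windows) array of CRN values."""
    mat = np.asarray(columns, dtype=float)
    samples = [crn(mat[i], f"s{i}") for i in range(mat.shape[0])]
    return batch_stats(samples, force=True, **kw)


class TestBatchStats:
    def test_hand_arithmetic_mean_and_sd(self):
        stats = stats_from([[100.0], [110.0], [120.0]])
        assert stats.mean[0] == pytest.approx(110.0)
        assert stats.sd[0] == pytest.approx(10.0)  # n-1 denominator

    def test_identical_samples_make_window_unusable(self):
        stats = stats_from([[100.0, 50.0]] * 10)
        assert not stats.usable[0] and not stats.usable[1]

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            batch_stats([crn([1.0, 2.0])], force=True)

    def test_small_batch_requires_force(self):
        samples = [crn([100.0, 100.0], f"s{i}") for i in range(3)]
        with pytest.raises(ValueError, match="need >= 8"):
            batch_stats(samples)

    def test_outlying_lot_mates_are_trimmed_iteratively(self):
        # two same-lot carriers of the same event must both be excluded from
        # the window statistics, or each masks the other
        rng = np.random.default_rng(0)
        col = rng.normal(1000, 10, size=30)
        col[3] -= 80  # ~8 sigma carriers
        col[7] -= 70
        stats = stats_from(col[:, None])
        assert not stats.kept[3, 0] and not stats.kept[7, 0]
        assert stats.mean[0] == pytest.approx(1000, abs=10)
        assert stats.sd[0] < 20

    def test_totals_normalized_to_lot_median(self):
        samples = [crn(np.full(4, 100.0 * f), f"s{f}") for f in (1, 2, 4)]
        scaled = normalize_totals(samples)
        assert all(s.total == pytest.approx(scaled[0].total) for s in scaled)


class TestZScores:
    def test_z_formula(self):
        stats = stats_from([[100.0], [110.0], [120.0]])
        z = z_scores(crn([100.0]), stats)
        assert z.z[0] == pytest.approx(-1.0)

    def test_equal_to_mean_gives_zero(self):
        stats = stats_from([[100.0], [110.0], [120.0]])
        assert z_scores(crn([110.0]), stats).z[0] == pytest.approx(0.0)

    def test_leave_one_out_excludes_own_contribution(self):
        stats = stats_from([[100.0], [110.0], [120.0], [115.0]])
        # leaving sample 0 out: mean(110,120,115)=115, sd=5
        z = z_scores(crn([100.0], "s0"), stats, sample_index=0)
        assert z.z[0] == pytest.approx((100 - 115) / 5.0)

    def test_unusable_window_propagates_missing(self):
        stats = stats_from([[100.0, 50.0], [110.0, 50.0], [120.0, 50.0]])
        z = z_scores(crn([100.0, 50.0]), stats)
        assert np.isnan(z.z[1])

    def test_null_profile_standardized(self, coarse_genome_map):
        """Across a 50-sample euploid lot the leave-one-out Z is ~N(0,1)."""
        corrected, stats = euploid_stats(coarse_genome_map, 50, seed=77)
        zs = np.vstack([z_scores(c, stats, i).z for i, c in enumerate(corrected)])
        usable = stats.usable
        assert abs(np.nanmean(zs[:, usable])) < 0.1
        per_window_sd = np.nanstd(zs[:, usable], axis=0, ddof=1)
        assert abs(np.median(per_window_sd) - 1) < 0.15


class TestDiscretize:
    @pytest.mark.parametrize(
        "z,symbol",
        [(-4.3, 0), (-4.0, 0), (-3.0, 1), (-2.5, 1), (0.0, 2), (2.4999, 2), (2.5, 3), (3.9, 3), (4.0, 4), (5.0, 4)],
    )
    def test_boundary_conventions(self, z, symbol):
        sym, _ = discretize(np.array([z]))
        assert sym[0] == symbol

    def test_missing_emits_neutral_with_mask(self):
        sym, missing = discretize(np.array([np.nan, 0.0]))
        assert sym[0] == 2 and missing[0] and not missing[1]

    def test_non_monotone_cuts_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([0.0]), cuts=(-4, -2.5, -3, 4))


class TestViterbi:
    def test_all_neutral_symbols_decode_neutral(self):
        assert np.all(viterbi(np.full(5, 2)) == 1)

    def test_two_strong_losses_decode_loss_island(self):
        path = viterbi(np.array([2, 0, 0, 2, 2]))
        assert list(path) == [1, 0, 0, 1, 1]
        best, argmax_paths = viterbi_bruteforce([2, 0, 0, 2, 2], HMMParams())
        assert len(argmax_paths) == 1 and np.array_equal(path, argmax_paths[0])

    def test_impossible_emission_raises(self):
        params = HMMParams(
            emission=np.array(
                [[0.5, 0.5, 0.0, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0, 0.0]]
            )
        )
        with pytest.raises(ValueError, match="impossible emission"):
            viterbi(np.array([2]), params)

    def test_degenerate_ties_break_to_neutral(self):
        params = HMMParams(
            emission=np.full((3, 5), 0.2),
            transition=np.full((3, 3), 1 / 3),
            initial=np.full(3, 1 / 3),
        )
        assert np.all(viterbi(np.array([0, 4, 2, 0]), params) == 1)

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(
        symbols=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        raw=st.lists(st.floats(0.01, 1.0), min_size=39, max_size=39),
    )
    def test_matches_bruteforce_on_random_models(self, symbols, raw):
        """Dynamic programming equals exhaustive path enumeration."""
        vals = np.array(raw)
        emission = vals[:15].reshape(3, 5)
        emission /= emission.sum(axis=1, keepdims=True)
        transition = vals[15:24].reshape(3, 3)
        transition /= transition.sum(axis=1, keepdims=True)
        initial = vals[24:27] / vals[24:27].sum()
        params = HMMParams(emission=emission, transition=transition, initial=initial)
        decoded = viterbi(np.array(symbols), params)
        best, argmax_paths = viterbi_bruteforce(symbols, params)
        assert path_logprob(decoded, symbols, params) >= best - 1e-9
        if len(argmax_paths) == 1:
            assert np.array_equal(decoded, argmax_paths[0])


@pytest.fixture
def five_mb_map():
    return build_windows(uniform_track([("c1", 5_000_000)], 100_000, 0.4), 1_000_000)


class TestSegment:
    def test_loss_run_coordinates_and_size(self, five_mb_map):
        path = np.array([1, 0, 0, 1, 1])
        z = ZProfile("s", np.array([0.0, -5.0, -4.5, 0.0, 0.0]))
        segs = segment(path, z, five_mb_map)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end) == (1_000_000, 3_000_000)
        assert s.size_mb == 2.00
        assert s.n_windows == 2
        assert s.state == "loss"
        assert s.mean_z == pytest.approx(-4.75)

    def test_all_neutral_yields_nothing(self, five_mb_map):
        segs = segment(np.ones(5, dtype=int), ZProfile("s", np.zeros(5)), five_mb_map)
        assert segs == []

    def test_weak_single_window_run_dropped(self, five_mb_map):
        path = np.array([1, 0, 1, 1, 1])
        segs = segment(path, ZProfile("s", np.array([0.0, -2.0, 0.0, 0.0, 0.0])), five_mb_map)
        assert segs == []

    def test_noisy_annexed_flank_trimmed_off(self, five_mb_map):
        # decoder annexed a -2.0 neighbor of a -6 window; boundary refinement
        # reports only the strong window
        path = np.array([1, 0, 0, 1, 1])
        segs = segment(path, ZProfile("s", np.array([0.0, -6.0, -2.0, 0.0, 0.0])), five_mb_map)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1_000_000, 2_000_000)

    def test_bridged_unrelated_windows_split(self, five_mb_map):
        # two deviant windows bridged across a neutral one become two segments
        path = np.array([0, 0, 0, 1, 1])
        segs = segment(path, ZProfile("s", np.array([-4.2, -0.5, -6.0, 0.0, 0.0])), five_mb_map)
        assert [(s.start, s.end) for s in segs] == [(0, 1_000_000), (2_000_000, 3_000_000)]

    def test_weak_wide_run_carried_by_aggregate_evidence(self, five_mb_map):
        path = np.array([0, 0, 0, 0, 1])
        z = ZProfile("s", np.array([-2.8, -2.7, -2.9, -2.8, 0.0]))
        segs = segment(path, z, five_mb_map)
        assert len(segs) == 1
        assert segs[0].n_windows == 4  # Stouffer ~ -5.6


WS = SyndromeRegion("Williams-Beuren (7q11.23)", "chr7", 72_700_000, 74_100_000, "loss", 0.5)


def seg(chrom="chr7", start=72_600_000, end=74_300_000, state="loss"):
    return CNVSegment(chrom=chrom, start=start, end=end, state=state, n_windows=2, mean_z=-5.0)


class TestMatchSyndromes:
    def test_full_overlap_matches(self):
        s = seg()
        match_syndromes([s], [WS])
        assert s.classification == "pathogenic_match"
        assert s.syndrome == WS.name
        assert s.syndrome_overlap == 1.0

    def test_state_must_agree(self):
        s = seg(state="gain")
        match_syndromes([s], [WS])
        assert s.classification == "unmatched"

    def test_insufficient_overlap_unmatched(self):
        s = seg(start=72_700_000, end=72_700_000 + 420_000)  # 30% of region
        match_syndromes([s], [WS])
        assert s.classification == "unmatched"

    def test_build_mismatch_raises(self):
        with pytest.raises(ValueError, match="build"):
            match_syndromes([seg()], [WS], build="GRCh38")

    def test_best_overlap_wins(self):
        # partial competitor: overlap 0.5/0.8 = 0.625 vs 1.0 for the WS region
        other = SyndromeRegion("partial", "chr7", 73_800_000, 74_600_000, "loss", 0.5)
        s = seg()
        match_syndromes([s], [other, WS])
        assert s.syndrome == WS.name


class TestScreenSample:
    def test_qc_failed_sample_is_no_call(self, coarse_genome_map):
        corrected, stats = euploid_stats(coarse_genome_map, 10, seed=5)
        ff = FFEstimate("s0", 0.02, "chrY", qc_pass=False, qc_reasons=["low_ff"])
        res = screen_sample(corrected[0], stats, coarse_genome_map, load_catalog(), sample_index=0, ff=ff)
        assert res.status == "no-call"
        assert res.segments == []

    def test_euploid_sample_has_no_segments(self, coarse_genome_map):
        corrected, stats = euploid_stats(coarse_genome_map, 10, seed=6)
        res = screen_sample(corrected[0], stats, coarse_genome_map, [], sample_index=0)
        assert res.status == "ok"
        assert all(s.classification != "pathogenic_match" for s in res.segments)
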