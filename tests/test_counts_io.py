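"""Unique-read filtering, per-window counting, count-matrix round trip."""

import numpy as np
import pysam
import pytest

from nipscnv.counts_io import (
    FilterParams,
    SampleCounts,
    count_sample,
    filter_alignment,
    read_counts,
    write_counts,
)
from nipscnv.genome_windows import build_windows, uniform_track
from nipscnv import simulate as sim

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:2000000\n@SQ\tSN:chrY\tLN:2000000\n"


def sam_line(qname, flag, rname, pos1, mapq, nm=0, tag=True):
    core = f"{qname}\t{flag}\t{rname}\t{pos1}\t{mapq}\t50M\t*\t0\t0\t{'A'*50}\t{'I'*50}"
    if flag & 0x4:
        core = f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{'A'*50}\t{'I'*50}"
        return core
    return core + (f"\tNM:i:{nm}" if tag else "")


@pytest.fixture
def two_mb_map():
    return build_windows(uniform_track([("chr1", 2_000_000), ("chrY", 2_000_000)], 100_000, 0.41), 1_000_000)


def write_sam(tmp_path, lines, name="s.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + "\n".join(lines) + "\n")
    return p


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "flag,mapq,nm,expected",
        [
            (0, 60, 0, (True, "pass")),
            (4, 0, 0, (False, "unmapped")),
            (1024, 60, 0, (False, "duplicate")),
            (256, 60, 0, (False, "secondary")),
            (2048, 60, 0, (False, "supplementary")),
            (512, 60, 0, (False, "low_quality")),
            (0, 0, 0, (False, "low_mapq")),  # MAPQ-0 multi-mapper
            (0, 60, 5, (False, "mismatches")),
        ],
    )
    def test_reason_codes(self, tmp_path, flag, mapq, nm, expected):
        path = write_sam(tmp_path, [sam_line("r", flag, "chr1", 100, mapq, nm)])
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            record = next(iter(fh))
        assert filter_alignment(record, FilterParams()) == expected

    def test_missing_nm_tag_passes(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r", 0, "chr1", 100, 60, tag=False)])
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            record = next(iter(fh))
        assert filter_alignment(record, FilterParams()) == (True, "pass")


class TestCountSample:
    def test_hand_counted_fixture(self, tmp_path, two_mb_map):
        # 2 retained reads in window 0, one duplicate, one unmapped
        path = write_sam(
            tmp_path,
            [
                sam_line("a", 0, "chr1", 101, 60),
                sam_line("b", 0, "chr1", 500_001, 60),
                sam_line("c", 1024, "chr1", 700_001, 60),
                sam_line("d", 4, "*", 0, 0),
            ],
        )
        counts = count_sample(path, two_mb_map, sample_id="fx")
        assert counts.raw[0] == 2
        assert counts.raw.sum() == 2
        assert counts.total_unique_reads == 2

    def test_boundary_read_goes_to_right_hand_window(self, tmp_path, two_mb_map):
        # 0-based start 1,000,000 == second window's start (SAM pos is 1-based)
        path = write_sam(tmp_path, [sam_line("a", 0, "chr1", 1_000_001, 60)])
        counts = count_sample(path, two_mb_map)
        assert counts.raw[1] == 1 and counts.raw[0] == 0

    def test_chry_reads_tallied(self, tmp_path, two_mb_map):
        path = write_sam(tmp_path, [sam_line("a", 0, "chrY", 100, 60), sam_line("b", 0, "chrY", 200, 60)])
        counts = count_sample(path, two_mb_map)
        assert counts.chry_reads == counts.total_unique_reads == 2

    def test_contig_absent_from_map_counts_toward_total_only(self, tmp_path):
        wmap = build_windows(uniform_track([("chr1", 2_000_000)], 100_000, 0.41), 1_000_000)
        path = tmp_path / "s.sam"
        path.write_text(
            "@SQ\tSN:chr1\tLN:2000000\n@SQ\tSN:chrM\tLN:20000\n"
            + sam_line("a", 0, "chr1", 100, 60)
            + "\n"
            + sam_line("b", 0, "chrM", 100, 60)
            + "\n"
        )
        counts = count_sample(path, wmap)
        assert counts.total_unique_reads == 2
        assert counts.raw.sum() == 1

    def test_no_retained_reads_is_an_error(self, tmp_path, two_mb_map):
        path = write_sam(tmp_path, [sam_line("a", 1024, "chr1", 100, 60)])
        with pytest.raises(ValueError, match="empty sample"):
            count_sample(path, two_mb_map)

    def test_counting_is_order_invariant(self, tmp_path, two_mb_map):
        lines = [sam_line(f"r{i}", 0, "chr1", 1 + 37 * i * 1000 % 1_999_000, 60) for i in range(20)]
        a = count_sample(write_sam(tmp_path, lines, "a.sam"), two_mb_map)
        b = count_sample(write_sam(tmp_path, lines[::-1], "b.sam"), two_mb_map)
        assert np.array_equal(a.raw, b.raw)


class TestFixtureEmission:
    def test_fixture_counts_reproduce_embedded_truth(self, tmp_path, two_mb_map):
        rng = np.random.default_rng(7)
        text = sim.emit_sam_fixture(two_mb_map, n_reads=100, rng=rng, dup_frac=0.1, unmapped_frac=0.05)
        path = tmp_path / "fx.sam"
        path.write_text(text)
        truth_line = next(l for l in text.splitlines() if l.startswith("@CO"))
        truth = np.array([int(x) for x in truth_line.rsplit(": ", 1)[1].split(",")])
        counts = count_sample(path, two_mb_map)
        assert counts.total_unique_reads == 100  # duplicates/unmapped dropped
        assert np.array_equal(counts.raw, truth)

    def test_seeded_fixture_is_byte_identical(self, two_mb_map):
        a = sim.emit_sam_fixture(two_mb_map, 50, np.random.default_rng(3), dup_frac=0.2)
        b = sim.emit_sam_fixture(two_mb_map, 50, np.random.default_rng(3), dup_frac=0.2)
        assert a == b

    def test_large_genome_refused(self):
        big = build_windows(uniform_track([("c", 10_000_000)], 100_000, 0.4), 1_000_000)
        with pytest.raises(ValueError, match="too large"):
            sim.emit_sam_fixture(big, 10, np.random.default_rng(0))


class TestCountsIO:
    def test_round_trip(self, tmp_path, two_mb_map):
        rng = np.random.default_rng(1)
        samples = [
            SampleCounts(f"s{i}", rng.poisson(100, len(two_mb_map)), 5_000_000 + i, chry_reads=10 * i, batch_id="b1")
            for i in range(3)
        ]
        path = tmp_path / "c.tsv"
        write_counts(samples, two_mb_map, path)
        back = read_counts(path, two_mb_map)
        assert [s.sample_id for s in back] == ["s0", "s1", "s2"]
        for orig, rt in zip(samples, back):
            assert np.array_equal(orig.raw, rt.raw)
            assert rt.total_unique_reads == orig.total_unique_reads
            assert rt.chry_reads == orig.chry_reads
            assert rt.batch_id == "b1"

    def test_empty_sample_list_round_trips(self, tmp_path, two_mb_map):
        path = tmp_path / "c.tsv"
        write_counts([], two_mb_map, path)
        assert read_counts(path) == []

    def test_length_mismatch_raises(self, tmp_path, two_mb_map):
        s = SampleCounts("s0", np.zeros(3, dtype=np.int64), 100)
        with pytest.raises(ValueError):
            write_counts([s], two_mb_map, tmp_path / "c.tsv")
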