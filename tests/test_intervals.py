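"""Interval model, BED-family I/O and set operations."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigse.intervals import (
    BedParseError,
    CoverageTrack,
    GenomicInterval,
    Peak,
    merge_overlapping,
    overlap_any,
    read_bed,
    read_bedgraph,
    read_gtf_genes,
    remove_blacklisted,
    write_bed,
)
from tests.conftest import random_intervals


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 10), ("chr1", 9, 20), True),   # one shared base
            (("chr1", 0, 10), ("chr1", 10, 20), False), # half-open adjacency
            (("chr1", 0, 10), ("chr2", 0, 10), False),  # chrom mismatch
            (("chr1", 5, 6), ("chr1", 0, 100), True),   # containment
        ],
    )
    def test_overlap_any(self, a, b, expected):
        assert overlap_any(iv(*a), iv(*b)) is expected
        assert overlap_any(iv(*b), iv(*a)) is expected  # symmetric


class TestReadBed:
    def test_bed3_fields(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\n")
        peaks = read_bed(p, "bed3")
        assert peaks[0].interval == GenomicInterval("chr1", 100, 200)

    def test_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "x.narrowPeak"
        p.write_text("chr1\t100\t200\tpk1\t900\t.\t12.5\t-1\t-1\t50\n")
        peaks = read_bed(p, "narrowPeak")
        assert peaks[0].summit_offset == 50
        assert peaks[0].score == 12.5

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t10\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p, "bed3")

    def test_too_few_fields(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(BedParseError):
            read_bed(p, "bed3")

    def test_roundtrip_through_writer(self, tmp_path):
        peaks = [
            Peak(iv("chr2", 5, 50), name="b", score=1.0),
            Peak(iv("chr1", 10, 20), name="a", score=2.0),
        ]
        path = tmp_path / "out.bed"
        write_bed(path, peaks)
        back = read_bed(path, "bed6")
        # writer sorts by coordinate
        assert [p.interval for p in back] == [iv("chr1", 10, 20), iv("chr2", 5, 50)]


class TestMergeOverlapping:
    def test_gap_at_threshold_merges(self):
        merged = merge_overlapping([iv("chr1", 0, 10), iv("chr1", 15, 20)], max_gap=5)
        assert merged == [iv("chr1", 0, 20)]

    def test_gap_above_threshold_keeps_separate(self):
        merged = merge_overlapping([iv("chr1", 0, 10), iv("chr1", 16, 20)], max_gap=5)
        assert len(merged) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            intervals = random_intervals(rng, 50)
            gap = int(rng.integers(0, 200))
            assert merge_overlapping(intervals, gap) == _merge_oracle(intervals, gap)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=30
        ),
        st.integers(0, 50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_disjointness_and_idempotence(self, raw, gap):
        intervals = [iv("chr1", s, s + w) for s, w in raw]
        merged = merge_overlapping(intervals, gap)
        # pairwise disjoint with gaps strictly above the threshold
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end > gap
        assert merge_overlapping(merged, gap) == merged
        # coverage can only grow
        total_in = sum(len(i) for i in merge_overlapping(intervals, 0))
        assert sum(len(i) for i in merged) >= total_in

    def test_agrees_with_bedtools_merge(self, tmp_path):
        """Independent oracle: bedtools merge -d on the same input."""
        rng = np.random.default_rng(7)
        intervals = sorted(random_intervals(rng, 40), key=GenomicInterval.sort_key)
        gap = 25
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"{i.chrom}\t{i.start}\t{i.end}\n" for i in intervals))
        out = subprocess.run(
            ["bedtools", "merge", "-d", str(gap), "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            iv(c, int(s), int(e))
            for c, s, e in (line.split("\t") for line in out.strip().split("\n"))
        ]
        assert merge_overlapping(intervals, gap) == expected


def _merge_oracle(intervals, gap):
    """Brute-force transitive-closure clustering (union-find)."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and max(a.start, b.start) - min(a.end, b.end) <= gap:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(intervals[i])
    merged = [
        GenomicInterval(
            c[0].chrom, min(x.start for x in c), max(x.end for x in c)
        )
        for c in clusters.values()
    ]
    return sorted(merged, key=GenomicInterval.sort_key)


class TestRemoveBlacklisted:
    def test_single_base_overlap_removes(self):
        peaks = [Peak(iv("chr1", 0, 100))]
        assert remove_blacklisted(peaks, [iv("chr1", 50, 60)]) == []

    def test_other_chromosome_kept(self):
        peaks = [Peak(iv("chr1", 0, 100))]
        assert remove_blacklisted(peaks, [iv("chr2", 0, 1000)]) == peaks

    def test_matches_allpairs_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            peaks = [Peak(i) for i in random_intervals(rng, 20)]
            blacklist = random_intervals(rng, 5)
            got = remove_blacklisted(peaks, blacklist)
            expected = [
                p for p in peaks
                if not any(overlap_any(p.interval, b) for b in blacklist)
            ]
            assert got == expected
            assert remove_blacklisted(got, blacklist) == got


class TestCoverageTrack:
    def test_region_sum_partial_overlap(self):
        track = CoverageTrack(
            {"chr1": (np.array([10, 30]), np.array([20, 40]), np.array([2.0, 5.0]))}
        )
        # covers [15,20) of the first record and [30,35) of the second
        assert track.region_sum(iv("chr1", 15, 35)) == 5 * 2.0 + 5 * 5.0

    def test_missing_bases_are_zero(self):
        track = CoverageTrack(
            {"chr1": (np.array([0]), np.array([10]), np.array([1.0]))}
        )
        assert track.region_sum(iv("chr1", 100, 200)) == 0.0
        assert track.region_sum(iv("chr2", 0, 10)) == 0.0

    def test_bedgraph_reader_rejects_overlap(self, tmp_path):
        p = tmp_path / "x.bedGraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t15\t2.0\n")
        with pytest.raises(ValueError):
            read_bedgraph(p)


def test_gtf_coordinates_converted_to_half_open(tmp_path):
    gtf = tmp_path / "genes.gtf"
    gtf.write_text(
        'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_name "A";\n'
        'chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tgene_name "A";\n'
        'chr2\tsrc\tgene\t501\t900\t.\t-\t.\tgene_id "B";\n'
    )
    genes = read_gtf_genes(gtf)
    assert [g.name for g in genes] == ["A", "B"]
    assert genes[0].region == GenomicInterval("chr1", 1000, 2000, "+")
    assert genes[0].tss == 1000
    assert genes[1].tss == 899  # minus strand: last covered base
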