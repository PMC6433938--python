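"""Promoter exclusion, stitching, density quantification and the slope-1
tangent cutoff."""

import numpy as np
import pytest

from sigse.intervals import CoverageTrack, GeneModel, Genome, GenomicInterval, Peak
from sigse.se_detection import (
    SEPartition,
    StitchedEnhancer,
    call_superenhancers,
    coverage_density,
    exclude_promoters,
    stitch,
    tangent_cutoff,
)


def peak(chrom, start, end, name="p"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


def gene(chrom, start, end, strand="+", name="g"):
    return GeneModel(name, GenomicInterval(chrom, start, end, strand))


class TestExcludePromoters:
    def test_peak_inside_promoter_window_removed(self):
        g = gene("chr1", 1000, 5000, "+")
        assert exclude_promoters([peak("chr1", 900, 1100)], [g], 2000) == []

    def test_peak_outside_window_kept(self):
        g = gene("chr1", 1000, 5000, "+")
        kept = exclude_promoters([peak("chr1", 5000, 5100)], [g], 2000)
        assert len(kept) == 1

    def test_minus_strand_tss_at_gene_end(self):
        g = gene("chr1", 1000, 5000, "-")  # TSS at 4999
        assert exclude_promoters([peak("chr1", 6000, 6100)], [g], 2000) == []
        assert len(exclude_promoters([peak("chr1", 500, 600)], [g], 2000)) == 1

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            peaks = [
                peak("chr1", s, s + int(rng.integers(1, 300)))
                for s in rng.integers(0, 50_000, size=30)
            ]
            genes = [
                gene("chr1", s, s + 2_000, strand=("+" if rng.random() < 0.5 else "-"))
                for s in rng.integers(0, 50_000, size=5)
            ]
            flank = 2_000
            windows = []
            for g in genes:
                windows.append((max(0, g.tss - flank), g.tss + flank))
            expected = [
                p
                for p in peaks
                if not any(p.start < hi and lo < p.end for lo, hi in windows)
            ]
            assert exclude_promoters(peaks, genes, flank) == expected


class TestStitch:
    def test_singleton(self):
        [se] = stitch([peak("chr1", 100, 600)], 12_500)
        assert se.region == GenomicInterval("chr1", 100, 600)
        assert len(se.constituents) == 1

    def test_default_threshold_boundary(self):
        near = [peak("chr1", 0, 500), peak("chr1", 12_500, 13_000)]   # gap 12,000
        far = [peak("chr1", 0, 500), peak("chr1", 13_500, 14_000)]    # gap 13,000
        assert len(stitch(near, 12_500)) == 1
        assert len(stitch(far, 12_500)) == 2

    def test_distance_zero_returns_merged_peaks(self):
        peaks = [peak("chr1", 0, 10), peak("chr1", 5, 20), peak("chr1", 100, 110)]
        regions = [se.region for se in stitch(peaks, 0)]
        assert regions == [GenomicInterval("chr1", 0, 20), GenomicInterval("chr1", 100, 110)]

    def test_constituents_partition_input(self):
        rng = np.random.default_rng(5)
        peaks = [
            peak("chr1", s, s + 200, name=f"p{i}")
            for i, s in enumerate(rng.integers(0, 200_000, size=60))
        ]
        stitched = stitch(peaks, 5_000)
        names = [c.name for se in stitched for c in se.constituents]
        assert sorted(names) == sorted(p.name for p in peaks)
        for se in stitched:
            for c in se.constituents:
                assert se.region.start <= c.start and c.end <= se.region.end


class TestCoverageDensity:
    def test_zero_track(self):
        track = CoverageTrack({})
        assert coverage_density(GenomicInterval("chr1", 0, 1000), track, 1e6) == 0.0

    def test_hand_computed_uniform_coverage(self):
        # 1,000 bp region, uniform coverage 10, 1e6 mapped reads -> 10 rpm/bp
        track = CoverageTrack(
            {"chr1": (np.array([0]), np.array([1000]), np.array([10.0]))}
        )
        region = GenomicInterval("chr1", 0, 1000)
        assert coverage_density(region, track, 1e6) == pytest.approx(10.0)
        # doubling mapped reads halves the density
        assert coverage_density(region, track, 2e6) == pytest.approx(5.0)


class TestTangentCutoff:
    def test_quadratic_curve_cutoff_at_quarter(self):
        # densities whose scaled curve is y = x^2: slope 2x = 1 at x = 0.5,
        # so the cutoff sits at scaled density 0.25
        n = 1000
        x = np.arange(n) / (n - 1)
        densities = x**2 * 80.0 + 5.0  # arbitrary scale/offset
        cutoff = tangent_cutoff(densities)
        scaled = (cutoff - 5.0) / 80.0
        assert scaled == pytest.approx(0.25, abs=0.02)

    def test_step_curve_selects_high_minority(self):
        densities = [1.0] * 90 + [100.0] * 10
        cutoff = tangent_cutoff(densities)
        assert sum(d > cutoff for d in densities) == 10

    def test_flat_curve_degenerate(self):
        assert tangent_cutoff([5.0, 5.0, 5.0, 5.0]) is None
        assert tangent_cutoff([1.0, 2.0]) is None  # n < 3

    def test_scale_invariance_of_partition(self):
        rng = np.random.default_rng(2)
        densities = np.concatenate([rng.uniform(0, 1, 95), rng.uniform(50, 60, 5)])
        base = tangent_cutoff(densities)
        scaled = tangent_cutoff(densities * 7.5)
        assert (densities > base).sum() == (densities * 7.5 > scaled).sum()
        assert np.array_equal(densities > base, densities * 7.5 > scaled)


class TestCallSuperenhancers:
    def _landscape(self):
        """One dense 10-peak cluster plus 200 isolated low peaks."""
        peaks, cov = [], []
        base = 1_000_000
        for i in range(10):
            s = base + i * 2_500
            peaks.append(peak("chr1", s, s + 500, name=f"c{i}"))
            cov.append((s, s + 500, 400.0))
        for i in range(200):
            s = 2_000_000 + i * 20_000
            peaks.append(peak("chr1", s, s + 500, name=f"b{i}"))
            cov.append((s, s + 500, 5.0))
        track = CoverageTrack(
            {
                "chr1": (
                    np.array([c[0] for c in cov]),
                    np.array([c[1] for c in cov]),
                    np.array([c[2] for c in cov]),
                )
            }
        )
        genome = Genome({"chr1": 10_000_000})
        return peaks, track, genome

    def test_planted_cluster_called_se(self):
        peaks, track, genome = self._landscape()
        part = call_superenhancers(
            peaks, track, None, [], genome, signal_reads=1e6
        )
        assert len(part.superenhancers) == 1
        se = part.superenhancers[0]
        assert len(se.constituents) == 10
        assert se.region.start == 1_000_000
        # SE set is an upper set of the density ranking
        max_te = max(r.net_density for r in part.typical)
        assert all(s.net_density > max_te for s in part.superenhancers)

    def test_empty_peaks_empty_partition(self):
        _, track, genome = self._landscape()
        part = call_superenhancers([], track, None, [], genome, signal_reads=1e6)
        assert part.ranked == [] and part.superenhancers == []

    def test_curve_table_is_consistent(self):
        peaks, track, genome = self._landscape()
        part = call_superenhancers(peaks, track, None, [], genome, signal_reads=1e6)
        rows = part.curve_table()
        assert len(rows) == 201
        assert sum(r["is_superenhancer"] for r in rows) == 1
        dens = [r["net_density"] for r in rows]
        assert dens == sorted(dens)


def test_partition_respects_cutoff_strictness():
    ses = [
        StitchedEnhancer(
            GenomicInterval("chr1", i * 1000, i * 1000 + 100),
            (peak("chr1", i * 1000, i * 1000 + 100),),
        )
        for i in range(3)
    ]
    # ties at the cutoff value go to typical
    from sigse.se_detection import DensityProfile

    quantified = [
        StitchedEnhancer(s.region, s.constituents, DensityProfile(s.region, d, 0.0))
        for s, d in zip(ses, [1.0, 2.0, 3.0])
    ]
    part = SEPartition.from_ranked(quantified, cutoff_value=2.0)
    assert [r.net_density for r in part.superenhancers] == [3.0]
    assert [r.net_density for r in part.typical] == [1.0, 2.0]
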