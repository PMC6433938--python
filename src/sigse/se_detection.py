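"""ROSE-style super-enhancer calling.

Pipeline: blacklist removal -> promoter (TSS +/- flank) exclusion ->
stitching of peaks within a fixed distance (default 12.5 kb) -> signal
density per stitched region in reads per million mapped reads per base pair
(rpm/bp) with background subtraction -> ranked-density curve -> slope-1
tangent cutoff separating super-enhancers (SE) from typical enhancers (TE).

Density convention: coverage tracks are consumed as already 200-bp-extended
piecewise-constant bedGraph (extension is the track producer's contract).
Net density is signal minus background, floored at zero; the denominator is
the full stitched span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import (
    CoverageTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    _IntervalIndex,
    merge_with_members,
    remove_blacklisted,
)

DEFAULT_TSS_FLANK = 2_000
DEFAULT_STITCH_DISTANCE = 12_500


@dataclass(frozen=True, slots=True)
class DensityProfile:
    """Background-subtracted signal density over one region, in rpm/bp."""

    region: GenomicInterval
    signal_rpm_bp: float
    background_rpm_bp: float

    @property
    def net_density(self) -> float:
        """signal − background, floored at 0 (background can exceed signal
        in noise regions)."""
        return max(0.0, self.signal_rpm_bp - self.background_rpm_bp)


@dataclass(frozen=True, slots=True)
class StitchedEnhancer:
    """A merged cluster of constituent peaks with its density profile."""

    region: GenomicInterval
    constituents: tuple[Peak, ...]
    density: DensityProfile | None = None

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("stitched enhancer requires >=1 constituent peak")

    @property
    def net_density(self) -> float:
        if self.density is None:
            raise ValueError("density not quantified for this region")
        return self.density.net_density


@dataclass
class SEPartition:
    """Ranked stitched enhancers split at the tangent cutoff.

    ``ranked`` is sorted by ascending net density. Every super-enhancer has
    net density strictly greater than ``cutoff_value``; ties at the cutoff
    are classed typical (conservative SE calls). ``cutoff_value`` is None
    when the curve is degenerate (fewer than 3 regions or a flat curve), in
    which case everything is typical.
    """

    ranked: list[StitchedEnhancer]
    cutoff_value: float | None
    superenhancers: list[StitchedEnhancer] = field(default_factory=list)
    typical: list[StitchedEnhancer] = field(default_factory=list)

    @classmethod
    def from_ranked(
        cls, ranked: list[StitchedEnhancer], cutoff_value: float | None
    ) -> "SEPartition":
        if cutoff_value is None:
            return cls(ranked, None, [], list(ranked))
        se = [r for r in ranked if r.net_density > cutoff_value]
        te = [r for r in ranked if r.net_density <= cutoff_value]
        return cls(ranked, cutoff_value, se, te)

    def curve_table(self) -> list[dict]:
        """Rank/density curve rows (ascending rank = ascending density)."""
        n = len(self.ranked)
        dens = np.array([r.net_density for r in self.ranked])
        lo, hi = (dens.min(), dens.max()) if n else (0.0, 0.0)
        rows = []
        for i, r in enumerate(self.ranked):
            rows.append(
                {
                    "chrom": r.region.chrom,
                    "start": r.region.start,
                    "end": r.region.end,
                    "rank": i,
                    "net_density": r.net_density,
                    "scaled_rank": i / (n - 1) if n > 1 else 0.0,
                    "scaled_density": (
                        (r.net_density - lo) / (hi - lo) if hi > lo else 0.0
                    ),
                    "is_superenhancer": (
                        self.cutoff_value is not None
                        and r.net_density > self.cutoff_value
                    ),
                }
            )
        return rows


def exclude_promoters(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_flank: int = DEFAULT_TSS_FLANK,
) -> list[Peak]:
    """Remove peaks overlapping any promoter window [TSS − flank, TSS + flank).

    The TSS is the gene start on the + strand and the gene end on the −
    strand. Order is preserved.
    """
    if tss_flank < 0:
        raise ValueError("tss_flank must be >= 0")
    windows = []
    for g in genes:
        lo = max(0, g.tss - tss_flank)
        hi = g.tss + tss_flank
        if hi > lo:
            windows.append(GenomicInterval(g.region.chrom, lo, hi))
    if not windows:
        return list(peaks)
    index = _IntervalIndex(windows)
    return [p for p in peaks if not index.overlaps(p.interval)]


def stitch(
    peaks: Sequence[Peak], stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[StitchedEnhancer]:
    """Stitch peaks within *stitch_distance* bp into candidate enhancer regions.

    Delegates the clustering to gap-tolerant interval merging; each stitched
    region spans min start to max end of its constituents and records them.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    clusters = merge_with_members([p.interval for p in peaks], max_gap=stitch_distance)
    return [
        StitchedEnhancer(region, tuple(peaks[i] for i in members))
        for region, members in clusters
    ]


def coverage_density(
    region: GenomicInterval, coverage: CoverageTrack, total_mapped_reads: float
) -> float:
    """Signal density over *region* in rpm/bp.

    ``(sum of per-base coverage / region length) / (total_mapped_reads / 1e6)``.
    Bases outside the track's extent count as zero coverage.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    per_bp = coverage.region_sum(region) / region.width
    return per_bp / (total_mapped_reads / 1e6)


def quantify(
    stitched: Sequence[StitchedEnhancer],
    signal: CoverageTrack,
    background: CoverageTrack | None,
    signal_reads: float,
    background_reads: float | None = None,
) -> list[StitchedEnhancer]:
    """Attach a density profile to each stitched region."""
    out = []
    for se in stitched:
        sig = coverage_density(se.region, signal, signal_reads)
        bg = 0.0
        if background is not None:
            if background_reads is None or background_reads <= 0:
                raise ValueError("background_reads required with a background track")
            bg = coverage_density(se.region, background, background_reads)
        out.append(
            StitchedEnhancer(
                se.region,
                se.constituents,
                DensityProfile(se.region, sig, bg),
            )
        )
    return out


def tangent_cutoff(
    densities: Sequence[float], smooth_window: int | None = None
) -> float | None:
    """Density at the slope-1 tangent point of the scaled ranked-density curve.

    Densities are sorted ascending; the rank axis is scaled to [0, 1] by
    (n − 1) and the density axis to [0, 1] by (max − min). The cutoff is the
    density at the first point, scanning from the low end, where the
    discrete derivative of the scaled curve reaches 1. The derivative is a
    centred 3-point finite difference after a moving-average smoother of
    window ``max(1, n // 100)`` points (override with *smooth_window*),
    which stabilises the cutoff on plateaued curves.

    Returns None for degenerate input (n < 3 or a flat curve), in which case
    the caller classes every region as typical.
    """
    d = np.sort(np.asarray(densities, dtype=float))
    n = d.size
    if n < 3 or d[-1] == d[0]:
        return None
    x = np.arange(n) / (n - 1)
    y = (d - d[0]) / (d[-1] - d[0])
    w = smooth_window if smooth_window is not None else max(1, n // 100)
    if w > 1:
        kernel = np.ones(w) / w
        # reflect-pad so the smoother does not shrink the curve at the ends
        pad = w // 2
        ypad = np.concatenate([y[pad:0:-1], y, y[-2 : -2 - (w - 1 - pad) : -1]])
        y_s = np.convolve(ypad, kernel, mode="valid")[: n]
    else:
        y_s = y
    slope = np.empty(n)
    slope[1:-1] = (y_s[2:] - y_s[:-2]) / (x[2:] - x[:-2])
    slope[0] = (y_s[1] - y_s[0]) / (x[1] - x[0])
    slope[-1] = (y_s[-1] - y_s[-2]) / (x[-1] - x[-2])
    at_least_1 = np.nonzero(slope >= 1.0)[0]
    if at_least_1.size:
        i = int(at_least_1[0])
    else:  # numerically flat-then-steep pathologies: closest-to-1 fallback
        i = int(np.argmin(np.abs(slope - 1.0)))
    return float(d[i])


def call_superenhancers(
    peaks: Sequence[Peak],
    signal: CoverageTrack,
    background: CoverageTrack | None,
    genes: Sequence[GeneModel],
    genome: Genome,
    signal_reads: float,
    background_reads: float | None = None,
    tss_flank: int = DEFAULT_TSS_FLANK,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
) -> SEPartition:
    """Full SE-calling pipeline for one condition.

    blacklist removal -> promoter exclusion -> stitching -> density
    quantification -> tangent cutoff -> SE/TE partition.
    """
    kept = remove_blacklisted(peaks, genome.blacklist)
    kept = exclude_promoters(kept, genes, tss_flank=tss_flank)
    stitched = stitch(kept, stitch_distance=stitch_distance)
    quantified = quantify(stitched, signal, background, signal_reads, background_reads)
    ranked = sorted(quantified, key=lambda r: (r.net_density, r.region.sort_key()))
    cutoff = tangent_cutoff([r.net_density for r in ranked])
    return SEPartition.from_ranked(ranked, cutoff)
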