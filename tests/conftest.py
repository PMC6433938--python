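"""Shared fixtures: a session-scoped default synthetic bundle and the
pipeline stages computed on it, so expensive steps run once."""

from __future__ import annotations

import numpy as np
import pytest

from sigse import binding_dynamics as dyn
from sigse import se_detection as sed
from sigse.intervals import (
    Genome,
    GenomicInterval,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_genes,
    remove_blacklisted,
)
from sigse.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study: 5/7/3 SE1/SE2/SE3 clusters plus
    SE5/SE6 before-only material, seed 0."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate(SimulationConfig(seed=0), outdir)


@pytest.fixture(scope="session")
def default_analysis(default_bundle):
    """SE partitions, dynamics labels, patterns and transitions computed on
    the default bundle."""
    b = default_bundle
    cfg = b.config
    genome = Genome(
        read_chrom_sizes(b.chrom_sizes),
        [p.interval for p in read_bed(b.blacklist_bed, "bed3")],
    )
    genes = read_genes(b.genes_tsv)
    peaks_b = read_bed(b.peaks_before, "narrowPeak")
    peaks_a = read_bed(b.peaks_after, "narrowPeak")
    background = read_bedgraph(b.background_track)
    reads = cfg.total_mapped_reads
    part_b = sed.call_superenhancers(
        peaks_b, read_bedgraph(b.signal_before), background, genes, genome,
        reads, reads, stitch_distance=cfg.stitch_distance,
    )
    part_a = sed.call_superenhancers(
        peaks_a, read_bedgraph(b.signal_after), background, genes, genome,
        reads, reads, stitch_distance=cfg.stitch_distance,
    )
    labels_b, labels_a = dyn.label_sites(
        remove_blacklisted(peaks_b, genome.blacklist),
        remove_blacklisted(peaks_a, genome.blacklist),
    )
    patterns_b = dyn.classify_partition(part_b, labels_b, "before")
    patterns_a = dyn.classify_partition(part_a, labels_a, "after")
    trans = dyn.transitions(patterns_b, patterns_a)
    return {
        "bundle": b,
        "genome": genome,
        "genes": genes,
        "part_before": part_b,
        "part_after": part_a,
        "labels_before": labels_b,
        "labels_after": labels_a,
        "patterns_before": patterns_b,
        "patterns_after": patterns_a,
        "transitions": trans,
    }


def random_intervals(rng: np.random.Generator, n: int, n_chroms: int = 2,
                     max_pos: int = 10_000, max_width: int = 500):
    """Helper for oracle tests: n random intervals on a toy genome."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out
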