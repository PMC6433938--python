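"""Assign genes to their closest super-enhancers and build gene sets.

Distance is edge-to-edge between the gene body and the SE span, measured in
gap bases (0 when the intervals overlap), following BEDTools ``closest``
anchoring on whole intervals rather than the TSS. Note the half-open
corner: book-ended intervals (gene end == SE start) have a 0 bp gap without
sharing a base. Equidistant SEs all yield links, so downstream gene sets
are independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .intervals import GeneModel, GenomicInterval
from .se_detection import StitchedEnhancer

DEFAULT_GENE_WINDOW = 50_000
DEFAULT_SNP_WINDOW = 500_000


@dataclass(frozen=True, slots=True)
class GeneLink:
    """A gene assigned to its closest SE within the search window."""

    gene: GeneModel
    se: StitchedEnhancer
    distance: int
    pattern: str | None = None


@dataclass(frozen=True, slots=True)
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = ""


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bases between two intervals; 0 if they overlap or are
    book-ended; None on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end)


def closest_within(
    genes: Sequence[GeneModel],
    ses: Sequence[StitchedEnhancer],
    window: int = DEFAULT_GENE_WINDOW,
    patterns: dict[int, str] | None = None,
) -> list[GeneLink]:
    """For each gene, link the SE(s) at minimal edge-to-edge distance,
    keeping only links with distance <= *window*; ties all link.

    *patterns*, if given, maps SE list index -> pattern label carried onto
    the link. The all-pairs scan is deliberate: SE sets are small (tens to
    hundreds), and the exact tie semantics matter more than asymptotics.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    links: list[GeneLink] = []
    for gene in genes:
        best: int | None = None
        hits: list[tuple[int, StitchedEnhancer]] = []
        for i, se in enumerate(ses):
            gap = interval_gap(gene.region, se.region)
            if gap is None or gap > window:
                continue
            if best is None or gap < best:
                best = gap
                hits = [(i, se)]
            elif gap == best:
                hits.append((i, se))
        for i, se in hits:
            links.append(
                GeneLink(
                    gene,
                    se,
                    best,  # type: ignore[arg-type]
                    pattern=patterns.get(i) if patterns else None,
                )
            )
    return links


def snp_proximity(
    regions: Sequence[GenomicInterval],
    snps: Sequence[GenomicInterval],
    window: int = DEFAULT_SNP_WINDOW,
) -> list[bool]:
    """Flag each region overlapping any SNP flanked by *window* bp.

    A SNP [p, p+1) is expanded to [p − window, p + 1 + window); at window 0
    this reduces to plain overlap.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    expanded = [
        GenomicInterval(s.chrom, max(0, s.start - window), s.end + window)
        for s in snps
    ]
    flags = []
    for region in regions:
        flags.append(
            any(
                e.chrom == region.chrom
                and e.start < region.end
                and region.start < e.end
                for e in expanded
            )
        )
    return flags


def merge_top_k_sets(
    ranked_lists: Sequence[Sequence[tuple[str, float]]],
    k: int = 200,
    name: str = "merged_top_k",
) -> GeneSet:
    """Union of the top-*k* gene symbols of each descending-sorted
    (gene, correlation) list.

    Lists shorter than k contribute all their genes, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranked_lists:
        raise ValueError("need at least one ranked list")
    members: set[str] = set()
    origins: list[str] = []
    for li, ranked in enumerate(ranked_lists):
        genes = [g for g, _ in ranked]
        if len(set(genes)) != len(genes):
            raise ValueError(f"ranked list {li} contains duplicate genes")
        if len(genes) < k:
            warnings.warn(
                f"ranked list {li} has only {len(genes)} genes (< k={k}); using all",
                stacklevel=2,
            )
        top = genes[:k]
        members.update(top)
        origins.append(f"list{li}:top{len(top)}")
    return GeneSet(name, frozenset(members), provenance="; ".join(origins))
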