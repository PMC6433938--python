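#!/usr/bin/env python
"""Expression analysis and sequence characteristics.

CPM-filters the counts matrix (CPM > 0.5 in >= 2 samples), runs the
two-group DE stand-in (p < 0.05 and |log2FC| >= 1 called significant),
links genes to their closest after-stimulation SEs within 50 kb, compares
the regulatory effect |log2FC| across SE patterns (Kruskal-Wallis + Dunn,
Bonferroni), and contrasts GC content of SE3 regions against typical
enhancers.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from sigse import expression_stats as xs
from sigse import gene_linking as linking
from sigse.intervals import GenomicInterval, Peak, read_bed, read_genes
from sigse.se_detection import StitchedEnhancer

DIR = Path("results/analysis")


def main() -> None:
    inputs = DIR / "inputs"
    counts = pd.read_csv(inputs / "counts.tsv", sep="\t", index_col=0)
    groups = {s: ("stim" if s.startswith("stim") else "veh") for s in counts.columns}
    retained, cpm_mat = xs.cpm_filter(counts)
    print(f"CPM filter: {len(retained)}/{len(counts)} genes retained")
    de = xs.simple_de(cpm_mat, groups, ("stim", "veh"))
    de_df = pd.DataFrame(
        [{"gene": r.gene, "log2fc": r.log2fc, "ave_expr": r.ave_expr,
          "p_value": r.p_value, "significant": r.significant,
          "highly_expressed": r.highly_expressed} for r in de]
    )
    de_df.to_csv(DIR / "de.tsv", sep="\t", index=False)
    print(f"significant genes: {int(de_df.significant.sum())}, "
          f"highly expressed: {int(de_df.highly_expressed.sum())}")

    patterns = pd.read_csv(DIR / "patterns.tsv", sep="\t")
    after = patterns[patterns.condition == "after"].reset_index(drop=True)
    ses = [
        StitchedEnhancer(
            GenomicInterval(r.chrom, r.start, r.end),
            (Peak(GenomicInterval(r.chrom, r.start, r.end)),),
        )
        for r in after.itertuples()
    ]
    links = linking.closest_within(
        read_genes(inputs / "genes.tsv"), ses,
        patterns={i: p for i, p in enumerate(after.pattern)},
    )
    pd.DataFrame(
        [{"gene": l.gene.name, "pattern": l.pattern, "distance": l.distance}
         for l in links]
    ).to_csv(DIR / "gene_links.tsv", sep="\t", index=False)
    print(f"gene links within 50 kb: {len(links)}")

    lfc = dict(zip(de_df.gene, de_df.log2fc))
    by_pattern: dict[str, list[float]] = {}
    linked = set()
    for l in links:
        if l.gene.name in lfc:
            by_pattern.setdefault(l.pattern, []).append(abs(lfc[l.gene.name]))
            linked.add(l.gene.name)
    by_pattern["unlinked"] = [abs(v) for g, v in lfc.items() if g not in linked]
    comp = xs.kruskal_dunn({k: v for k, v in by_pattern.items() if len(v) >= 2})
    print(f"regulatory effect |log2FC| across patterns: KW p = {comp.kw_p:.3g}")

    fasta = Fasta(str(inputs / "genome.fa"))
    gc_groups = {}
    for pat in ("SE1", "SE2", "SE3"):
        rows = after[after.pattern == pat]
        gc_groups[pat] = [
            xs.region_gc(GenomicInterval(r.chrom, r.start, r.end), fasta)
            for r in rows.itertuples()
        ]
    gc_groups["TE"] = [
        xs.region_gc(p.interval, fasta)
        for p in read_bed(DIR / "after.TE.bed", "bed6")
    ]
    comp_gc = xs.kruskal_dunn({"SE3": gc_groups["SE3"], "TE": gc_groups["TE"]})
    for k, v in gc_groups.items():
        print(f"GC {k}: mean {np.mean(v):.3f} (n={len(v)})")
    print(f"SE3 vs TE GC contrast: p = {comp_gc.kw_p:.3g}")


if __name__ == "__main__":
    main()
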