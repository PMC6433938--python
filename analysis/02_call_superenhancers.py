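#!/usr/bin/env python
"""Call super-enhancers in both conditions.

ROSE-style pipeline per condition: blacklist removal, promoter exclusion
(TSS +/- 2 kb), 12.5 kb stitching, rpm/bp density with background
subtraction, slope-1 tangent cutoff. Writes SE/TE BED files and the
ranked-density curve per condition.
"""

from pathlib import Path

import pandas as pd

from sigse import se_detection as sed
from sigse.intervals import (
    Genome, read_bed, read_bedgraph, read_chrom_sizes, read_genes, write_bed,
)

DIR = Path("results/analysis")
TOTAL_READS = 1e6  # the simulated tracks are written in rpm/bp at 1e6 reads


def main() -> None:
    inputs = DIR / "inputs"
    genome = Genome(
        read_chrom_sizes(inputs / "genome.sizes"),
        [p.interval for p in read_bed(inputs / "blacklist.bed", "bed3")],
    )
    genes = read_genes(inputs / "genes.tsv")
    background = read_bedgraph(inputs / "background.bedGraph")
    for cond in ("before", "after"):
        peaks = read_bed(inputs / f"peaks_{cond}.narrowPeak", "narrowPeak")
        signal = read_bedgraph(inputs / f"signal_{cond}.bedGraph")
        part = sed.call_superenhancers(
            peaks, signal, background, genes, genome, TOTAL_READS, TOTAL_READS,
        )
        write_bed(DIR / f"{cond}.SE.bed", [r.region for r in part.superenhancers])
        write_bed(DIR / f"{cond}.TE.bed", [r.region for r in part.typical])
        pd.DataFrame(part.curve_table()).to_csv(
            DIR / f"{cond}.curve.tsv", sep="\t", index=False
        )
        print(
            f"{cond}: {len(part.superenhancers)} SE / {len(part.typical)} TE, "
            f"cutoff {part.cutoff_value:.3f} rpm/bp"
        )


if __name__ == "__main__":
    main()
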