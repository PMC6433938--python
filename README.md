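# sigse — signal-inducible super-enhancer analysis

`sigse` analyses *signal-inducible super-enhancers*: clusters of
transcription-factor binding sites that appear when a signalling pathway's
terminal TF (for example the vitamin D receptor after 1,25(OH)₂D₃
stimulation) floods a genomic neighbourhood with binding. It is written for
regulatory genomicists who have two-condition ChIP-seq peak calls and want
to (i) call super-enhancers, (ii) classify them by binding dynamics,
(iii) test whether disease-risk variants concentrate inside them, and
(iv) connect them to gene expression.

## What it computes

**Super-enhancer calling (ROSE-style).** Peaks are cleaned against a
blacklist, peaks inside promoter windows (TSS ± 2 kb) are excluded, and the
survivors are stitched within 12.5 kb. Each stitched region gets a signal
density in reads per million mapped reads per base pair (rpm/bp) with input
background subtracted and floored at zero. Regions are ranked by density;
with both axes scaled to [0, 1], the cutoff sits where the curve's slope
first reaches 1, and regions strictly above it are super-enhancers (SEs),
the rest typical enhancers (TEs).

**Binding-dynamics classification.** Comparing peak sets before and after
stimulation (≥1 bp overlap), each site is *primary* (before only),
*persistent* (both) or *secondary* (after only). Each after-stimulation SE
is then SE1 (persistent only), SE2 (persistent + secondary) or SE3
(secondary only); before-stimulation SEs are SE4/SE5/SE6 analogously with
primary in place of secondary. Transitions track every before-SE to its
overlapping after-SEs (persisting, reclassified, or lost).

**Region enrichment.** Overlaps between features (risk SNPs) and a region
set are normalised per 10 Mb of region-set size and compared with a null
built from 1,000 permutations that re-place each region uniformly over
positions avoiding the blacklist and the original set. |z| > 1.96 is read
as two-sided p < 0.05; the one-sided empirical p is reported alongside.

**Gene linking and expression.** Genes link to their closest SE within
50 kb (edge-to-edge, ties kept); SNP proximity uses ±500 kb flanks. The
expression side provides CPM filtering (CPM > 0.5 in ≥2 samples), a
transparent Welch-t DE stand-in on log2(CPM + 0.5) with significance at
p < 0.05 and |log2FC| ≥ 1, Kruskal–Wallis with tie-corrected Dunn post-hoc
tests under Bonferroni, Pearson density correlations, GC content, and
pre-ranked GSEA (weighted running-sum score, gene-tag permutation null,
leading-edge extraction).

**Synthetic data.** Because the original inputs are deep-sequencing
archives, `sigse.synthetic_data` generates a complete miniature study —
genome FASTA, blacklist, two-condition peak sets with planted SE1–SE6
clusters, coverage tracks, SNPs with a planted enrichment rate, and a
negative-binomial counts matrix — with a machine-readable truth table, so
every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic landscape (5/7/3 planted SE1/SE2/SE3 clusters, 4 SE5 and 3 SE6
before-only clusters, 200 background peaks, 45 SNPs at a 90% planted rate):

```
$ python analysis/01_simulate.py
planted clusters: SE1=5, SE2=7, SE3=3, SE5=4, SE6=3
SNPs inside planted SEs: 39/45

$ python analysis/02_call_superenhancers.py
before: 19 SE / 150 TE, cutoff 0.446 rpm/bp
after: 19 SE / 150 TE, cutoff 0.457 rpm/bp

$ python analysis/03_classify_dynamics.py
after-stimulation census: {'SE1': 9, 'SE2': 7, 'SE3': 3}
before-stimulation census: {'SE4': 12, 'SE5': 4, 'SE6': 3}
transition fates: {'SE5->SE1': 4, 'SE4->SE2': 7, 'SE4->SE1': 5, 'SE6->lost': 3}

$ python analysis/04_snp_enrichment.py
SE_all  z=  181.42  p=0.000999  (179,500 bp) ENRICHED
TE      z=   -0.32  p=1  (75,000 bp) not enriched

$ python analysis/06_gsea.py
ES = 0.917, NES = 2.58, permutation p = 0.000999
```

Reading these numbers: the 19 called SEs are exactly the planted clusters
(the 150 TEs are the isolated background peaks). After stimulation the nine
SE1 regions are the five persistent-only clusters plus the four SE5
clusters whose persistent core survives; the census reproduces the planted
7 SE2 and 3 SE3. Every persistent-core SE4 that gained secondary binding
reclassified to SE2 (7), the rest persisted as SE1 (5), and the three
primary-only SE6 regions were lost — the qualitative transition structure
the method is built to expose. SNPs are strongly enriched in SEs but not in
TEs, and SE-linked genes cluster at the top of the fold-change ranking
(minimal permutation p at 1,000 permutations).

The same pipeline is available as a CLI (`sigse simulate`, `sigse call-se`,
`sigse classify`, `sigse enrich`, `sigse link-genes`, `sigse gsea`,
`sigse run`) and as one call, `sigse.pipeline.run_all(RunConfig(...))`,
which writes per-stage TSVs plus a versioned `report.json` and is
byte-reproducible given a seed.

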