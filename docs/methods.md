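# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Overlap means ≥1 shared base — half-open adjacency is
not overlap, matching `bedtools intersect` defaults. Strand is carried but
ignored by overlap, merge and stitch operations, since enhancer calls are
unstranded; it is used only to derive the TSS (gene start on +, last
covered base on −). Chromosome names are compared as exact strings; a
validation helper warns about names present in only one of two inputs
rather than attempting any "chr" normalisation, so data mismatches surface
instead of silently disappearing.

## Super-enhancer calling

The pipeline follows the ROSE procedure: blacklist removal, exclusion of
peaks overlapping promoter windows (TSS ± `tss_flank`, default 2,000 bp),
stitching of the survivors within `stitch_distance` (default 12,500 bp),
density quantification, and the slope-1 tangent cutoff on the ranked
density curve. TSS exclusion applies to peaks *before* stitching; density
is then computed over the full stitched span (the alternative — summing
only constituent spans — changes the denominator; the stitched span is the
convention used here and is what the ranked curve is built from).

Density is reads per million mapped reads per base pair:
`(region coverage sum / region length) / (total mapped reads / 1e6)`,
with the matched input control quantified identically and subtracted, and
negative values floored at 0 before ranking (background can exceed signal
in noise regions). Coverage tracks are consumed as piecewise-constant
bedGraph already extended to fragment length (200 bp); extension is the
track producer's contract, which keeps the package free of BAM handling.

For the cutoff, ranks and densities are scaled to [0, 1] (rank by n−1,
density by max−min after subtracting the minimum). The discrete derivative
of the scaled curve is a centred 3-point finite difference after a
moving-average smoother of window `max(1, n // 100)` points (reflect
padding at the ends); the cutoff is the density at the first point,
scanning from the low end, where that derivative reaches 1. On a flat or
too-short curve (n < 3 or max = min) there is no cutoff and every region
is typical. Ties at the cutoff density are classed typical: an SE must be
*strictly* above the cutoff, which keeps SE calls conservative. Because
both axes are normalised, multiplying all densities by a positive constant
leaves the partition unchanged.

## Binding dynamics and patterns

Sites are labelled by ≥1 bp cross-condition overlap with no
reciprocal-fraction threshold (the `bedtools intersect` framing):
overlapping before/after peaks are *persistent* in both conditions, the
remainder are *primary* (before only) or *secondary* (after only). A
persistent site is represented in each condition by that condition's own
peak coordinates, carrying partner links; a peak overlapping several
partners yields one label with all partners recorded, preserving the
identities |primary| + |persistent(before)| = |before peaks| and
symmetrically for after.

An SE's pattern comes from the labelled sites it overlaps: after-condition
SEs are SE1 (persistent only), SE2 (both), SE3 (secondary only);
before-condition SEs are SE4/SE5/SE6 with primary in place of secondary.
UNBOUND is an explicit class for SEs overlapping no labelled site, which
occurs when SEs are called from a different mark than the labelled TF.

Transitions map each before-SE to all after-SEs it overlaps (multi-hits
are flagged). A before-SE with no hit is *lost*. It *persists* when every
hit is persistence-compatible: SE4→SE1, SE5→{SE1, SE2}, SE6→SE3 —
i.e. the persistent core (or, for SE6, purely condition-specific binding
of the same region) carries the SE through the contrast. Anything else is
*reclassified* (the canonical case: a persistent-only SE4 that gains
secondary binding and re-emerges as SE2).

## Permutation enrichment

The observed statistic is the number of features (risk SNPs, as 1-bp
intervals at the reported coordinate) overlapping the region set, divided
by the merged region-set size and scaled per 10 Mb. The null re-places
each region independently, width preserved, uniformly over all genomic
positions where it fits a chromosome and overlaps neither the blacklist
nor the original region set; chromosomes are implicitly weighted by their
valid-position counts, making placement uniform over valid starts
genome-wide. Randomised regions may overlap one another (independent
placement). Both conventions the field mixes are reported: the z-score
against the permutation null with |z| > 1.96 read as two-sided p < 0.05,
and the one-sided empirical p `(1 + #{perm ≥ obs}) / (1 + n_perm)`
(default n_perm = 1,000). A zero-variance null is flagged and z reported
as signed infinity. Per-pattern tests are uncorrected, as is conventional
for this analysis; a Bonferroni column over the tested labels is emitted
for transparency.

One calibration property is worth knowing: excluding the original region
set from the null slightly anti-correlates the observed count with the
null mean, so for region sets covering a large fraction of the genome the
test is anti-conservative (measured: ~11% |z| > 1.96 under a true null at
10% genome coverage, vs ~5–7% at 1% coverage). Real SE sets cover well
under 1% of a genome, where the effect is negligible; the calibration test
runs in that regime.

## Gene linking and gene sets

A gene links to the SE(s) minimising edge-to-edge distance between gene
body and SE span — `bedtools closest` semantics, not TSS-anchored — kept
when the distance is within the window (default 50,000 bp; a gap of
exactly 50,000 links, 50,001 does not). Equidistant SEs all link, so
downstream gene sets are order-independent. One corner is inherited from
gap-based distance: book-ended intervals have distance 0 without sharing a
base. SNP proximity flags regions overlapping SNP ± 500 kb; at window 0
this reduces to plain overlap. Ranked gene lists merge by taking the union
of their top-k symbols (default k = 200), recording per-list provenance.

## Expression statistics

CPM uses pre-filter library sizes; genes are retained at CPM > 0.5 in ≥2
samples. The DE stand-in is a deliberately transparent two-group Welch t
on log2(CPM + 0.5) — the pseudocount keeps zeros finite and mirrors common
practice — with log2FC as the group-mean difference and flags recomputed
from fixed thresholds (significant: p < 0.05 and |log2FC| ≥ 1; highly
expressed: mean log2 expression > 5). A moderated linear-model fit is out
of scope; a precomputed DE table can be flagged instead
(`flag_de_table`). Plain CPM does not correct library composition, so
fold-change estimates are unbiased only when up- and down-regulated mass
roughly balance — which the synthetic generator guarantees (below).

Group comparisons use Kruskal–Wallis (tie-corrected, via scipy) with
Dunn's post-hoc pairwise z tests: average ranks,
variance `[N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/nᵢ + 1/nⱼ)`, two-sided
normal p, Bonferroni over all pairs — the R `dunn.test` defaults. All
pooled values identical yields omnibus and pairwise p = 1. Density
correlations are Pearson on log2(rpm/bp) with zero densities floored at
ε = 0.001 rpm/bp before the log (the floor only matters for empty
regions; results are insensitive to ε over 10⁻²–10⁻⁴ because floored
regions are rare in called enhancer sets), Bonferroni-adjusted over the
number of tested pairs. GC content is (G+C)/(A+C+G+T) case-insensitive
with ambiguity codes excluded from the denominator; an all-N region is an
error, not a zero.

## GSEA

Pre-ranked only. Walking the ranking, hits add `|score|^p / Σ_hits
|score|^p` and misses subtract `1/(N − N_hits)`; the ES is the running sum
at its first point of maximal absolute deviation. Default weight p = 1
(the method's published default); p = 0 gives the unweighted statistic
with its telescoping-to-zero and reversal-negation identities, used by the
analytic tests. The null is gene-tag permutation — random same-size
subsets of the ranking — the only null available without sample-level
data; NES divides ES by the mean |null ES| of matching sign. The leading
edge is the set members at ranks up to the ES peak; for a negative ES the
trailing-edge analog is returned, flagged. A set that misses the ranking
entirely, or covers it (zero miss denominator), is an error.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
TF ChIP-seq + RNA-seq + GWAS study, not its sequence content. Defaults
(chosen once as the study conditions): 4 chromosomes × 6 Mb; 5/7/3
SE1/SE2/SE3 clusters plus 4 SE5 and 3 SE6 before-only clusters; 5 peaks of
500 bp per cluster, 2 kb apart (inside the 12.5 kb stitch distance, so
stitching provably reconstructs each cluster); 150 kb between clusters
(beyond stitch + 100 kb, so clusters never merge); 200 isolated background
peaks cycling persistent/primary/secondary labels; cluster density
10 rpm/bp vs background-peak density 0.5 against an input level of
0.1 rpm/bp (a 20× separation, comfortably beyond the 10× the two-regime
cutoff needs); Gaussian track noise of 0.02 rpm/bp; 4 blacklist regions of
5 kb containing decoy peaks in both conditions; one gene 10 kb downstream
of each cluster plus filler genes to 300 total; 45 SNPs placed inside a
planted after-condition SE span with probability 0.9, else uniformly
outside the blacklist; 3+3 negative-binomial counts (dispersion 0.1) with
log2FC = 2 planted on after-bound cluster genes and on 20% of filler
genes.

Design notes. A persistent-only "SE4" cluster is geometrically identical
to an SE1 cluster viewed before stimulation, so SE4 counts as a planted
kind default to 0 and before-condition SE4s arise from the SE1 and SE2
clusters. Planted DE is restricted to filler genes above a baseline of 20
expected counts (an effect below the detection floor would only measure
sampling noise), and signs are assigned greedily so up- and down-regulated
mass balance the cluster-gene up-mass — without this, libraries differ in
composition and CPM fold changes shrink genome-wide (measured: 1.78×
library imbalance, −0.83 log2 bias, before balancing). FASTA bases are
i.i.d. uniform ACGT except inside SE3 cluster spans, which are GC-rich
(0.72 vs 0.50), giving the GC-content contrast a planted signal. The
truth table records every planted entity exactly once; SNP inside/outside
flags are recomputed from actual overlap, not placement intent. The whole
bundle is a deterministic function of the config, byte-identical across
reruns.

What the generator does *not* emulate: read-level noise and mappability
structure, peak-width and inter-peak-distance heterogeneity, correlated
replicate structure, LD between SNPs, and any real-genome sequence
composition. Passing recovery tests therefore demonstrates correctness of
the pipeline's logic under its stated assumptions — well-separated
density regimes and non-adjacent clusters — not robustness to the failure
modes of real ChIP-seq.

## Orchestration and reproducibility

`run_all` executes simulate → SE calling (per condition) → dynamics
classification → transitions → SNP enrichment by pattern → gene linking →
expression statistics → GC contrast → GSEA → truth-recovery scoring, and
writes per-stage TSVs plus `report.json` (`"schema": 1`). Every
stochastic stage derives its seed as the run seed plus a fixed per-stage
offset (simulate +0, enrichment +101, GSEA +202), so stages are
independently reproducible and the report is byte-identical across reruns
with the same config. The regulatory-effect comparison groups genes by
their linked after-SE pattern with priority SE1 > SE2 > SE3 when a gene
ties to several, against all unlinked tested genes.

Problem sizes throughout (6 Mb chromosomes, hundreds of peaks, tens of
SEs, 300 genes, 1,000 permutations) are chosen so the full study runs in
seconds while every statistic still operates in its asymptotic regime;
the interval and linking algorithms are exact at any scale, so nothing
about the method changes with larger inputs.

## Known limitations

- The tangent cutoff's first-slope-≥1 scan assumes a convex ranked curve;
  on multi-regime curves the first crossing wins (by design, matching the
  hockey-stick reading), and the closest-to-|slope−1| fallback only
  triggers on numerically pathological flat curves.
- The DE stand-in has no variance moderation; with 3+3 replicates its
  power at |log2FC| = 2 is ~0.8, and recall figures should be read
  against that, not against a moderated fit.
- Enrichment z assumes an approximately normal permutation null; for very
  sparse feature sets the empirical p is the more trustworthy of the two
  reported conventions.
- Multi-mapping transitions (one before-SE overlapping several after-SEs)
  record all hits but the fate rule treats the hit set as a whole; no
  attempt is made to apportion the region between targets.
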