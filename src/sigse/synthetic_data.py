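"""Synthetic two-condition ChIP-seq/RNA-seq landscape with known truth.

Generates a complete input bundle — genome FASTA + sizes, blacklist, peak
sets before/after stimulation, pre-extended coverage bedGraphs with a
matched background track, gene annotation, SNP set and a counts matrix —
together with a machine-readable truth table, so every pipeline stage can
be tested without external downloads.

Planted structure
-----------------
* SE clusters of each dynamics pattern. A cluster is ``peaks_per_cluster``
  peaks of ``peak_width`` bp separated by ``intra_cluster_gap`` bp (less
  than the stitch distance, so stitching reconstructs the cluster exactly):

  - SE1: all peaks persistent (identical coordinates in both conditions) —
    after-pattern SE1, before-pattern SE4, fate "persists".
  - SE2: a persistent core plus secondary (after-only) peaks —
    after SE2, before SE4, fate "reclassified".
  - SE3: all peaks after-only — after SE3, absent before.
  - SE4: alias of the persistent-only geometry (kept configurable; 0 by
    default since SE1 clusters already present as SE4 before stimulation).
  - SE5: persistent core plus primary (before-only) peaks —
    before SE5, after SE1, fate "persists".
  - SE6: all peaks before-only — before SE6, lost after.

* Isolated background peaks (further than the stitch distance from
  anything) at low density form the typical-enhancer bulk; their dynamics
  labels rotate persistent / primary / secondary deterministically.
* Blacklist regions containing decoy peaks in both conditions.
* One gene 10 kb downstream of every cluster (always linkable within the
  50 kb window) plus isolated filler genes; cluster genes that are bound
  after stimulation carry a planted positive log2 fold change, and a
  configurable fraction of filler genes are differentially expressed with
  alternating sign. Counts are negative binomial.
* SNPs fall inside a planted after-condition SE span with probability
  ``snp_enrichment_rate``, otherwise uniformly outside the blacklist.
* FASTA bases are i.i.d. uniform ACGT except inside SE3 cluster spans,
  which are GC-rich, giving the GC-content contrast a planted signal.

Everything is deterministic given the seed: the same config produces a
byte-identical bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_STITCH = 12_500


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic landscape.

    Defaults give 5/7/3 planted SE1/SE2/SE3 clusters (plus SE5/SE6
    before-only material), a 20x density separation between clusters and
    background peaks, 45 SNPs at 90% planted SE placement, and a 3+3
    negative-binomial counts matrix.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 6_000_000
    # cluster geometry
    n_se1: int = 5
    n_se2: int = 7
    n_se3: int = 3
    n_se4: int = 0
    n_se5: int = 4
    n_se6: int = 3
    peaks_per_cluster: int = 5
    peak_width: int = 500
    intra_cluster_gap: int = 2_000
    inter_cluster_gap: int = 150_000
    stitch_distance: int = DEFAULT_STITCH
    # background landscape
    n_background_peaks: int = 200
    n_blacklist: int = 4
    blacklist_width: int = 5_000
    density_high: float = 10.0   # rpm/bp over a cluster span
    density_low: float = 0.5     # rpm/bp over an isolated background peak
    background_level: float = 0.1  # input-track rpm/bp
    noise_sd: float = 0.02       # Gaussian sd added to bedGraph values
    total_mapped_reads: float = 1e6
    # genes / expression
    n_genes: int = 300
    gene_length: int = 5_000
    gene_offset: int = 10_000    # cluster end -> gene start
    n_samples_per_group: int = 3
    de_fraction: float = 0.2
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    # SNPs
    n_snps: int = 45
    snp_enrichment_rate: float = 0.9
    # sequence composition
    gc_background: float = 0.5
    gc_se3: float = 0.72

    def __post_init__(self) -> None:
        if not (0 <= self.snp_enrichment_rate <= 1):
            raise ValueError("snp_enrichment_rate must be in [0, 1]")
        if not (self.intra_cluster_gap < self.stitch_distance):
            raise ValueError("intra_cluster_gap must be < stitch_distance")
        if not (self.inter_cluster_gap > self.stitch_distance + 100_000):
            raise ValueError(
                "inter_cluster_gap must exceed stitch_distance + 100 kb"
            )
        if self.n_genes < self.n_clusters:
            raise ValueError("n_genes must cover one gene per cluster")
        if self.peaks_per_cluster < 2:
            raise ValueError("peaks_per_cluster must be >= 2")

    @property
    def n_clusters(self) -> int:
        return (
            self.n_se1 + self.n_se2 + self.n_se3
            + self.n_se4 + self.n_se5 + self.n_se6
        )

    @property
    def cluster_span(self) -> int:
        p, w, g = self.peaks_per_cluster, self.peak_width, self.intra_cluster_gap
        return p * w + (p - 1) * g


@dataclass
class PlantedCluster:
    cluster_id: str
    kind: str                     # "SE1".."SE6"
    chrom: str
    start: int                    # full-span start (all peaks)
    end: int
    span_before: tuple[int, int] | None
    span_after: tuple[int, int] | None
    expected_before: str | None   # SE4/SE5/SE6
    expected_after: str | None    # SE1/SE2/SE3
    expected_fate: str | None     # persists_as / reclassified_as / lost


@dataclass
class TruthTable:
    """Ground truth for every planted entity (each appears exactly once)."""

    clusters: list[PlantedCluster]
    peak_labels_before: list[dict]   # chrom/start/end/label, decoys excluded
    peak_labels_after: list[dict]
    snps: list[dict]                 # chrom/pos/inside_se (actual overlap)
    genes: list[dict]                # name/true_log2fc/is_de/cluster_id
    blacklist: list[dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clusters": [asdict(c) for c in self.clusters],
            "peak_labels_before": self.peak_labels_before,
            "peak_labels_after": self.peak_labels_after,
            "snps": self.snps,
            "genes": self.genes,
            "blacklist": self.blacklist,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedBundle:
    """Paths of the generated files plus the in-memory truth."""

    outdir: Path
    config: SimulationConfig
    truth: TruthTable
    genome_fasta: Path = field(init=False)
    chrom_sizes: Path = field(init=False)
    blacklist_bed: Path = field(init=False)
    peaks_before: Path = field(init=False)
    peaks_after: Path = field(init=False)
    signal_before: Path = field(init=False)
    signal_after: Path = field(init=False)
    background_track: Path = field(init=False)
    genes_tsv: Path = field(init=False)
    snps_bed: Path = field(init=False)
    counts_tsv: Path = field(init=False)
    truth_json: Path = field(init=False)

    def __post_init__(self) -> None:
        d = Path(self.outdir)
        self.genome_fasta = d / "genome.fa"
        self.chrom_sizes = d / "genome.sizes"
        self.blacklist_bed = d / "blacklist.bed"
        self.peaks_before = d / "peaks_before.narrowPeak"
        self.peaks_after = d / "peaks_after.narrowPeak"
        self.signal_before = d / "signal_before.bedGraph"
        self.signal_after = d / "signal_after.bedGraph"
        self.background_track = d / "background.bedGraph"
        self.genes_tsv = d / "genes.tsv"
        self.snps_bed = d / "snps.bed"
        self.counts_tsv = d / "counts.tsv"
        self.truth_json = d / "truth.json"


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

_EXPECTATIONS = {
    # kind: (expected_before, expected_after, expected_fate)
    "SE1": ("SE4", "SE1", "persists_as"),
    "SE2": ("SE4", "SE2", "reclassified_as"),
    "SE3": (None, "SE3", None),
    "SE4": ("SE4", "SE1", "persists_as"),
    "SE5": ("SE5", "SE1", "persists_as"),
    "SE6": ("SE6", None, "lost"),
}


def _slot_clearance(cfg: SimulationConfig, slot_type: str) -> int:
    if slot_type == "cluster":
        return cfg.inter_cluster_gap
    if slot_type in ("background", "blacklist"):
        return cfg.stitch_distance + 1_000
    return 6_000  # filler gene: just clear of promoter flanks


def _layout(cfg: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Place all slots sequentially across chromosomes.

    Returns slot dicts with chrom/start assigned; raises if the genome is
    too small before anything is written.
    """
    slots: list[dict] = []
    kinds = (
        ["SE1"] * cfg.n_se1 + ["SE2"] * cfg.n_se2 + ["SE3"] * cfg.n_se3
        + ["SE4"] * cfg.n_se4 + ["SE5"] * cfg.n_se5 + ["SE6"] * cfg.n_se6
    )
    cluster_slot_len = cfg.cluster_span + cfg.gene_offset + cfg.gene_length
    for i, kind in enumerate(kinds):
        slots.append(
            {"type": "cluster", "kind": kind, "id": f"cluster_{i:03d}",
             "length": cluster_slot_len}
        )
    for i in range(cfg.n_blacklist):
        slots.append(
            {"type": "blacklist", "id": f"blacklist_{i:02d}",
             "length": cfg.blacklist_width}
        )
    for i in range(cfg.n_background_peaks):
        slots.append(
            {"type": "background", "id": f"bg_{i:03d}", "length": cfg.peak_width}
        )
    n_filler = cfg.n_genes - cfg.n_clusters
    for i in range(n_filler):
        slots.append(
            {"type": "gene", "id": f"fillergene_{i:03d}", "length": cfg.gene_length}
        )
    rng.shuffle(slots)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    ci, cursor = 0, 50_000
    prev_clear = 0
    for slot in slots:
        clear = _slot_clearance(cfg, slot["type"])
        gap = max(prev_clear, clear)
        start = cursor + gap
        while start + slot["length"] + clear > cfg.chrom_length:
            ci += 1
            if ci >= cfg.n_chroms:
                raise ValueError(
                    "genome too small for the requested layout: increase "
                    "chrom_length or n_chroms, or reduce cluster/background counts"
                )
            cursor, prev_clear = 50_000, 0
            start = cursor + max(prev_clear, clear)
        slot["chrom"] = chrom_names[ci]
        slot["start"] = start
        cursor = start + slot["length"]
        prev_clear = clear
    return slots


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Write the full synthetic bundle into *outdir* and return it."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slots = _layout(cfg, rng)

    clusters: list[PlantedCluster] = []
    peaks_before: list[tuple[str, int, int, str, float]] = []
    peaks_after: list[tuple[str, int, int, str, float]] = []
    labels_before: list[dict] = []
    labels_after: list[dict] = []
    genes: list[tuple[str, str, int, int, str]] = []
    gene_truth: list[dict] = []
    blacklist: list[tuple[str, int, int]] = []
    gc_rich_spans: list[tuple[str, int, int]] = []
    # (chrom, start, end, value) records per track
    cov_before: list[tuple[str, int, int, float]] = []
    cov_after: list[tuple[str, int, int, float]] = []

    n_persist_core = math.ceil(cfg.peaks_per_cluster / 2)

    def cluster_peaks(kind: str, chrom: str, start: int, cid: str):
        """Yield (index, start, end, role) for every peak of a cluster."""
        w, g = cfg.peak_width, cfg.intra_cluster_gap
        for i in range(cfg.peaks_per_cluster):
            s = start + i * (w + g)
            if kind in ("SE1", "SE4"):
                role = "persistent"
            elif kind == "SE2":
                role = "persistent" if i < n_persist_core else "secondary"
            elif kind == "SE3":
                role = "secondary"
            elif kind == "SE5":
                role = "persistent" if i < n_persist_core else "primary"
            else:  # SE6
                role = "primary"
            yield i, s, s + w, role

    bg_cycle = ("persistent", "persistent", "primary", "secondary")
    for slot in slots:
        chrom, start = slot["chrom"], slot["start"]
        if slot["type"] == "cluster":
            kind, cid = slot["kind"], slot["id"]
            before_spans: list[tuple[int, int]] = []
            after_spans: list[tuple[int, int]] = []
            for i, s, e, role in cluster_peaks(kind, chrom, start, cid):
                name = f"{cid}_p{i}"
                if role in ("persistent", "primary"):
                    peaks_before.append((chrom, s, e, name, cfg.density_high))
                    labels_before.append(
                        {"chrom": chrom, "start": s, "end": e,
                         "label": "PERSISTENT" if role == "persistent" else "PRIMARY"}
                    )
                    before_spans.append((s, e))
                if role in ("persistent", "secondary"):
                    peaks_after.append((chrom, s, e, name, cfg.density_high))
                    labels_after.append(
                        {"chrom": chrom, "start": s, "end": e,
                         "label": "PERSISTENT" if role == "persistent" else "SECONDARY"}
                    )
                    after_spans.append((s, e))
            exp_b, exp_a, fate = _EXPECTATIONS[kind]
            span_b = (before_spans[0][0], before_spans[-1][1]) if before_spans else None
            span_a = (after_spans[0][0], after_spans[-1][1]) if after_spans else None
            full_end = start + cfg.cluster_span
            clusters.append(
                PlantedCluster(cid, kind, chrom, start, full_end,
                               span_b, span_a, exp_b, exp_a, fate)
            )
            if kind == "SE3":
                gc_rich_spans.append((chrom, start, full_end))
            # coverage: constant value over each present peak such that the
            # mean density over the condition span equals density_high
            for cond, spans, cov in (
                ("before", before_spans, cov_before),
                ("after", after_spans, cov_after),
            ):
                if not spans:
                    continue
                span_len = spans[-1][1] - spans[0][0]
                covered = sum(e - s for s, e in spans)
                value = cfg.density_high * span_len / covered
                for s, e in spans:
                    cov.append((chrom, s, e, value))
            # the cluster's gene, 10 kb downstream, + strand
            gname = f"gene_{cid}"
            gstart = full_end + cfg.gene_offset
            genes.append((gname, chrom, gstart, gstart + cfg.gene_length, "+"))
            bound_after = exp_a is not None
            gene_truth.append(
                {"name": gname, "cluster_id": cid,
                 "true_log2fc": cfg.de_log2fc if bound_after else 0.0,
                 "is_de": bound_after}
            )
        elif slot["type"] == "background":
            role = bg_cycle[int(slot["id"].split("_")[1]) % len(bg_cycle)]
            s, e = start, start + cfg.peak_width
            name = slot["id"]
            if role in ("persistent", "primary"):
                peaks_before.append((chrom, s, e, name, cfg.density_low))
                labels_before.append(
                    {"chrom": chrom, "start": s, "end": e,
                     "label": "PERSISTENT" if role == "persistent" else "PRIMARY"}
                )
                cov_before.append((chrom, s, e, cfg.density_low))
            if role in ("persistent", "secondary"):
                peaks_after.append((chrom, s, e, name, cfg.density_low))
                labels_after.append(
                    {"chrom": chrom, "start": s, "end": e,
                     "label": "PERSISTENT" if role == "persistent" else "SECONDARY"}
                )
                cov_after.append((chrom, s, e, cfg.density_low))
        elif slot["type"] == "blacklist":
            s, e = start, start + cfg.blacklist_width
            blacklist.append((chrom, s, e))
            # decoy peaks inside the blacklist, both conditions
            ds = s + 500
            peaks_before.append((chrom, ds, ds + cfg.peak_width, slot["id"] + "_decoy", 1.0))
            peaks_after.append((chrom, ds, ds + cfg.peak_width, slot["id"] + "_decoy", 1.0))
        else:  # filler gene
            gname = slot["id"]
            genes.append((gname, chrom, start, start + cfg.gene_length,
                          "+" if int(slot["id"].split("_")[1]) % 2 == 0 else "-"))
            gene_truth.append(
                {"name": gname, "cluster_id": None, "true_log2fc": 0.0,
                 "is_de": False}
            )

    # baseline expression: cluster-linked genes get a stable high baseline so
    # planted fold changes are detectable; filler genes span a wide dynamic
    # range so the CPM filter and expression flags have real work to do
    for g in gene_truth:
        if g["cluster_id"] is not None:
            g["baseline"] = float(np.exp(rng.normal(np.log(200.0), 0.5)))
        else:
            g["baseline"] = float(np.exp(rng.normal(np.log(30.0), 2.2)))
    # planted DE among adequately expressed filler genes (effects on genes
    # below the detection floor would only measure sampling noise). Signs are
    # assigned greedily so up- and down-regulated mass balance the
    # cluster-gene up-mass: libraries then have near-equal composition and
    # CPM-based fold changes are unbiased, as in standard DE benchmarks.
    filler = [g for g in gene_truth if g["cluster_id"] is None]
    eligible = [g for g in filler if g["baseline"] >= 20.0]
    n_de = min(int(round(cfg.de_fraction * len(filler))), len(eligible))
    de_idx = rng.choice(len(eligible), size=n_de, replace=False)
    fc = 2.0 ** cfg.de_log2fc
    net_mass = sum(
        g["baseline"] * (fc - 1.0) for g in gene_truth if g["is_de"]
    )
    chosen = sorted(
        (eligible[i] for i in de_idx), key=lambda g: -g["baseline"]
    )
    for g in chosen:
        g["is_de"] = True
        if net_mass > 0:
            g["true_log2fc"] = -cfg.de_log2fc
            net_mass += g["baseline"] * (1.0 / fc - 1.0)
        else:
            g["true_log2fc"] = cfg.de_log2fc
            net_mass += g["baseline"] * (fc - 1.0)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sizes = {c: cfg.chrom_length for c in chrom_names}

    # --- SNPs ------------------------------------------------------------
    after_spans = [
        (c.chrom, *c.span_after) for c in clusters if c.span_after is not None
    ]
    snp_rows: list[dict] = []
    for i in range(cfg.n_snps):
        if after_spans and rng.random() < cfg.snp_enrichment_rate:
            chrom, s, e = after_spans[int(rng.integers(0, len(after_spans)))]
            pos = int(rng.integers(s, e))
        else:
            pos = _uniform_non_blacklist(rng, sizes, blacklist)
            chrom = pos[0]
            pos = pos[1]
        inside = any(
            chrom == c2 and s2 <= pos < e2 for c2, s2, e2 in after_spans
        )
        snp_rows.append({"chrom": chrom, "pos": int(pos), "inside_se": bool(inside),
                         "name": f"rs{900000 + i}"})

    truth = TruthTable(
        clusters=clusters,
        peak_labels_before=labels_before,
        peak_labels_after=labels_after,
        snps=snp_rows,
        genes=gene_truth,
        blacklist=[{"chrom": c, "start": s, "end": e} for c, s, e in blacklist],
    )
    bundle = SimulatedBundle(outdir, cfg, truth)

    # --- write files ------------------------------------------------------
    _write_sizes(bundle.chrom_sizes, sizes)
    _write_bed3(bundle.blacklist_bed, blacklist)
    _write_narrowpeak(bundle.peaks_before, peaks_before)
    _write_narrowpeak(bundle.peaks_after, peaks_after)
    _write_bedgraph(bundle.signal_before, cov_before, rng, cfg.noise_sd)
    _write_bedgraph(bundle.signal_after, cov_after, rng, cfg.noise_sd)
    _write_background_track(bundle.background_track, sizes, cfg, rng)
    _write_genes(bundle.genes_tsv, genes)
    _write_snps(bundle.snps_bed, snp_rows)
    _write_counts(bundle.counts_tsv, gene_truth, cfg, rng)
    _write_fasta(bundle.genome_fasta, sizes, gc_rich_spans, cfg, rng)
    truth.to_json(bundle.truth_json)
    return bundle


def _uniform_non_blacklist(rng, sizes, blacklist) -> tuple[str, int]:
    chroms = list(sizes)
    total = sum(sizes.values())
    weights = np.array([sizes[c] for c in chroms]) / total
    for _ in range(1000):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(0, sizes[chrom]))
        if not any(c == chrom and s <= pos < e for c, s, e in blacklist):
            return chrom, pos
    raise RuntimeError("could not place SNP outside blacklist")


def _write_sizes(path, sizes):
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _write_bed3(path, rows):
    with open(path, "w") as fh:
        for chrom, s, e in sorted(rows):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def _write_narrowpeak(path, rows):
    with open(path, "w") as fh:
        for chrom, s, e, name, score in sorted(rows):
            fh.write(
                f"{chrom}\t{s}\t{e}\t{name}\t{int(min(1000, score * 10))}\t.\t"
                f"{score:.4f}\t-1\t-1\t{(e - s) // 2}\n"
            )


def _write_bedgraph(path, rows, rng, noise_sd):
    with open(path, "w") as fh:
        for chrom, s, e, v in sorted(rows):
            noisy = max(0.0, v + rng.normal(0.0, noise_sd))
            fh.write(f"{chrom}\t{s}\t{e}\t{noisy:.5f}\n")


def _write_background_track(path, sizes, cfg, rng):
    """Input control: near-constant low coverage in 100 segments per chrom."""
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            edges = np.linspace(0, size, 101).astype(int)
            for s, e in zip(edges[:-1], edges[1:]):
                v = max(0.0, cfg.background_level + rng.normal(0.0, cfg.noise_sd / 4))
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.5f}\n")


def _write_genes(path, genes):
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tstrand\n")
        for name, chrom, s, e, strand in sorted(genes, key=lambda g: (g[1], g[2])):
            fh.write(f"{name}\t{chrom}\t{s}\t{e}\t{strand}\n")


def _write_snps(path, snp_rows):
    with open(path, "w") as fh:
        for row in sorted(snp_rows, key=lambda r: (r["chrom"], r["pos"])):
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['pos'] + 1}\t{row['name']}\n")


def _write_counts(path, gene_truth, cfg, rng):
    """Negative-binomial counts, vehicle vs stimulated groups."""
    n = cfg.n_samples_per_group
    samples = [f"veh_{i + 1}" for i in range(n)] + [f"stim_{i + 1}" for i in range(n)]
    inv_disp = 1.0 / cfg.nb_dispersion
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for g in sorted(gene_truth, key=lambda r: r["name"]):
            base = g["baseline"]
            mu_veh = np.full(n, base)
            mu_stim = np.full(n, base * 2.0 ** g["true_log2fc"])
            mu = np.concatenate([mu_veh, mu_stim])
            p = inv_disp / (inv_disp + mu)
            counts = rng.negative_binomial(inv_disp, p)
            fh.write(g["name"] + "\t" + "\t".join(str(int(c)) for c in counts) + "\n")


def _write_fasta(path, sizes, gc_rich_spans, cfg, rng, line_width: int = 60):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    g = cfg.gc_background
    p_bg = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    g3 = cfg.gc_se3
    p_gc = np.array([(1 - g3) / 2, g3 / 2, g3 / 2, (1 - g3) / 2])
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            seq = rng.choice(bases, size=size, p=p_bg)
            for c, s, e in gc_rich_spans:
                if c == chrom:
                    seq[s:e] = rng.choice(bases, size=e - s, p=p_gc)
            fh.write(f">{chrom}\n")
            n_full = size // line_width
            body = seq[: n_full * line_width].reshape(n_full, line_width)
            newline = np.full((n_full, 1), ord("\n"), dtype=np.uint8)
            fh.write(np.hstack([body, newline]).tobytes().decode("ascii"))
            tail = seq[n_full * line_width :]
            if tail.size:
                fh.write(tail.tobytes().decode("ascii") + "\n")


# ---------------------------------------------------------------------------
# Recovery verification
# ---------------------------------------------------------------------------


def verify_recovery(
    truth: TruthTable,
    labels_before,
    labels_after,
    patterns_before,
    patterns_after,
    transition_records=None,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Returns per-stage recovery rates: fraction of planted SEs called with
    the correct pattern per condition, dynamics-label accuracy, and (when
    transitions are supplied) the fate confusion counts.
    """
    report: dict = {}
    report["dynamics_label_accuracy_before"] = _label_accuracy(
        truth.peak_labels_before, labels_before
    )
    report["dynamics_label_accuracy_after"] = _label_accuracy(
        truth.peak_labels_after, labels_after
    )
    for cond, patterns in (("before", patterns_before), ("after", patterns_after)):
        expected = [
            (c, c.span_before if cond == "before" else c.span_after,
             c.expected_before if cond == "before" else c.expected_after)
            for c in truth.clusters
        ]
        expected = [(c, span, exp) for c, span, exp in expected if exp is not None]
        n_found = 0
        n_correct = 0
        for c, span, exp in expected:
            hit = next(
                (
                    sp
                    for sp in patterns
                    if sp.se.region.chrom == c.chrom
                    and sp.se.region.start < span[1]
                    and span[0] < sp.se.region.end
                ),
                None,
            )
            if hit is not None:
                n_found += 1
                if hit.pattern.value == exp:
                    n_correct += 1
        report[f"se_recall_{cond}"] = n_found / len(expected) if expected else 1.0
        report[f"pattern_accuracy_{cond}"] = (
            n_correct / len(expected) if expected else 1.0
        )
    if transition_records is not None:
        fates: dict[str, dict[str, int]] = {}
        for c in truth.clusters:
            if c.expected_before is None or c.expected_fate is None:
                continue
            rec = next(
                (
                    r
                    for r in transition_records
                    if r.before_se.se.region.chrom == c.chrom
                    and r.before_se.se.region.start < c.span_before[1]
                    and c.span_before[0] < r.before_se.se.region.end
                ),
                None,
            )
            observed = rec.fate.value if rec is not None else "missing"
            fates.setdefault(c.expected_fate, {}).setdefault(observed, 0)
            fates[c.expected_fate][observed] += 1
        report["transition_fates"] = fates
        total = sum(sum(v.values()) for v in fates.values())
        correct = sum(fates.get(f, {}).get(f, 0) for f in fates)
        report["transition_accuracy"] = correct / total if total else 1.0
    return report


def _label_accuracy(truth_rows: list[dict], labels) -> float:
    """Fraction of planted (non-decoy) peaks receiving their true label."""
    by_coord = {
        (lab.site.chrom, lab.site.start, lab.site.end): lab.label.value
        for lab in labels
    }
    if not truth_rows:
        return 1.0
    hits = sum(
        1
        for row in truth_rows
        if by_coord.get((row["chrom"], row["start"], row["end"])) == row["label"]
    )
    return hits / len(truth_rows)
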