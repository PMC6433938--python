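"""End-to-end orchestration: simulate -> call SEs -> classify dynamics ->
link genes -> SNP enrichment -> expression statistics -> GSEA.

Every stochastic stage draws its seed from the run seed plus a fixed
per-stage offset, so stages are reproducible independently and the whole
run is a pure function of (inputs, parameters, seed). ``run_all`` writes
per-stage TSVs plus a versioned ``report.json``; rerunning with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_dynamics as dyn
from . import enrichment as enr
from . import expression_stats as xstats
from . import gene_linking as linking
from . import gsea as gsea_mod
from . import se_detection as sed
from .intervals import Genome, GenomicInterval, read_bed, read_bedgraph, read_chrom_sizes, read_genes
from .synthetic_data import SimulationConfig, simulate, verify_recovery

logger = logging.getLogger("sigse")

REPORT_SCHEMA = 1

# fixed per-stage seed offsets (recorded in the log)
SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_ENRICHMENT = 101
SEED_OFFSET_GSEA = 202


@dataclass
class RunConfig:
    """Parameters of a full synthetic-study run."""

    outdir: str = "results/run"
    seed: int = 0
    tss_flank: int = 2_000
    stitch: int = 12_500
    gene_window: int = 50_000
    snp_window: int = 500_000
    n_perm: int = 1_000
    z_crit: float = 1.96
    gsea_weight: float = 1.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("tss_flank", "stitch", "gene_window", "snp_window", "n_perm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def run_all(config: RunConfig) -> dict:
    """Execute the whole analysis and return the report dict.

    Writes ``report.json`` and per-stage TSVs under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: seed=%d outdir=%s", config.seed, outdir)

    # -- stage 1: synthetic inputs ---------------------------------------
    sim_cfg = SimulationConfig(
        **{**asdict(config.simulation),
           "seed": config.seed + SEED_OFFSET_SIMULATE,
           "stitch_distance": config.stitch}
    )
    bundle = simulate(sim_cfg, outdir / "inputs")
    logger.info("simulated %d clusters on %d chromosomes",
                sim_cfg.n_clusters, sim_cfg.n_chroms)

    genome = Genome(
        read_chrom_sizes(bundle.chrom_sizes),
        [p.interval for p in read_bed(bundle.blacklist_bed, dialect="bed3")],
    )
    genes = read_genes(bundle.genes_tsv)
    peaks_b = read_bed(bundle.peaks_before, dialect="narrowPeak")
    peaks_a = read_bed(bundle.peaks_after, dialect="narrowPeak")
    signal_b = read_bedgraph(bundle.signal_before)
    signal_a = read_bedgraph(bundle.signal_after)
    background = read_bedgraph(bundle.background_track)
    reads = sim_cfg.total_mapped_reads

    # -- stage 2: SE calling per condition -------------------------------
    part_b = sed.call_superenhancers(
        peaks_b, signal_b, background, genes, genome, reads, reads,
        tss_flank=config.tss_flank, stitch_distance=config.stitch,
    )
    part_a = sed.call_superenhancers(
        peaks_a, signal_a, background, genes, genome, reads, reads,
        tss_flank=config.tss_flank, stitch_distance=config.stitch,
    )
    for cond, part in (("before", part_b), ("after", part_a)):
        pd.DataFrame(part.curve_table()).to_csv(
            outdir / f"curve_{cond}.tsv", sep="\t", index=False
        )
    logger.info("SE/TE: before %d/%d, after %d/%d",
                len(part_b.superenhancers), len(part_b.typical),
                len(part_a.superenhancers), len(part_a.typical))

    # -- stage 3: dynamics classification --------------------------------
    from .intervals import remove_blacklisted

    clean_b = remove_blacklisted(peaks_b, genome.blacklist)
    clean_a = remove_blacklisted(peaks_a, genome.blacklist)
    labels_b, labels_a = dyn.label_sites(clean_b, clean_a)
    patterns_b = dyn.classify_partition(part_b, labels_b, "before")
    patterns_a = dyn.classify_partition(part_a, labels_a, "after")
    trans = dyn.transitions(patterns_b, patterns_a)
    census = {
        "before": dyn.pattern_census(patterns_b),
        "after": dyn.pattern_census(patterns_a),
    }
    _patterns_table(patterns_b + patterns_a).to_csv(
        outdir / "patterns.tsv", sep="\t", index=False
    )
    _transitions_table(trans).to_csv(
        outdir / "transitions.tsv", sep="\t", index=False
    )

    # -- stage 4: SNP enrichment by pattern ------------------------------
    snps = [p.interval for p in read_bed(bundle.snps_bed, dialect="bed3")]
    region_sets: dict[str, list[GenomicInterval]] = {
        "SE_all": [sp.se.region for sp in patterns_a],
        "SE1": [sp.se.region for sp in patterns_a if sp.pattern is dyn.Pattern.SE1],
        "SE2": [sp.se.region for sp in patterns_a if sp.pattern is dyn.Pattern.SE2],
        "SE3": [sp.se.region for sp in patterns_a if sp.pattern is dyn.Pattern.SE3],
        "TE": [r.region for r in part_a.typical],
    }
    enrich = enr.enrichment_by_pattern(
        snps, region_sets, genome,
        n_perm=config.n_perm, seed=config.seed + SEED_OFFSET_ENRICHMENT,
    )
    enrich_rows = enr.results_table(enrich)
    pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # -- stage 5: gene linking -------------------------------------------
    pattern_by_idx = {i: sp.pattern.value for i, sp in enumerate(patterns_a)}
    links = linking.closest_within(
        genes, [sp.se for sp in patterns_a],
        window=config.gene_window, patterns=pattern_by_idx,
    )
    link_df = pd.DataFrame(
        [
            {"gene": l.gene.name, "chrom": l.se.region.chrom,
             "se_start": l.se.region.start, "se_end": l.se.region.end,
             "distance": l.distance, "pattern": l.pattern}
            for l in links
        ]
    )
    link_df.to_csv(outdir / "gene_links.tsv", sep="\t", index=False)
    snp_flags = linking.snp_proximity(
        [sp.se.region for sp in patterns_a], snps, window=config.snp_window
    )

    # -- stage 6: expression ---------------------------------------------
    counts = pd.read_csv(bundle.counts_tsv, sep="\t", index_col=0)
    groups = {s: ("stim" if s.startswith("stim") else "veh") for s in counts.columns}
    retained, cpm_mat = xstats.cpm_filter(counts)
    de = xstats.simple_de(cpm_mat, groups, contrast=("stim", "veh"))
    de_df = pd.DataFrame(
        [
            {"gene": r.gene, "log2fc": r.log2fc, "ave_expr": r.ave_expr,
             "p_value": r.p_value, "significant": r.significant,
             "highly_expressed": r.highly_expressed}
            for r in de
        ]
    )
    de_df.to_csv(outdir / "de.tsv", sep="\t", index=False)

    # regulatory effect (|log2fc|) grouped by the gene's linked pattern
    pattern_of_gene: dict[str, str] = {}
    priority = {"SE1": 0, "SE2": 1, "SE3": 2}
    for l in links:
        if l.pattern in priority:
            prev = pattern_of_gene.get(l.gene.name)
            if prev is None or priority[l.pattern] < priority[prev]:
                pattern_of_gene[l.gene.name] = l.pattern
    lfc_by_gene = dict(zip(de_df["gene"], de_df["log2fc"]))
    effect_groups: dict[str, list[float]] = {"SE1": [], "SE2": [], "SE3": [], "none": []}
    for gene, lfc in lfc_by_gene.items():
        effect_groups[pattern_of_gene.get(gene, "none")].append(abs(lfc))
    effect_groups = {k: v for k, v in effect_groups.items() if len(v) >= 2}
    comparison = (
        xstats.kruskal_dunn(effect_groups) if len(effect_groups) >= 2 else None
    )

    # GC content: after-SE patterns vs typical enhancers
    gc_report = _gc_by_pattern(bundle, patterns_a, part_a)

    # -- stage 7: GSEA ----------------------------------------------------
    se_gene_set = linking.GeneSet(
        "SE_linked", frozenset(pattern_of_gene), provenance="closest_within"
    )
    ranked = gsea_mod.RankedList.from_pairs(
        list(zip(de_df["gene"], de_df["log2fc"]))
    )
    gsea_res = None
    if 0 < len(se_gene_set.members & set(ranked.genes)) < len(ranked):
        gsea_res = gsea_mod.gsea_test(
            ranked, se_gene_set, weight=config.gsea_weight,
            n_perm=config.n_perm, seed=config.seed + SEED_OFFSET_GSEA,
        )

    # -- stage 8: recovery vs planted truth ------------------------------
    recovery = verify_recovery(
        bundle.truth, labels_b, labels_a, patterns_b, patterns_a, trans
    )
    recovery["de_recall"] = _de_recall(bundle.truth, de_df)

    report = {
        "schema": REPORT_SCHEMA,
        "seed": config.seed,
        "parameters": {
            "tss_flank": config.tss_flank, "stitch": config.stitch,
            "gene_window": config.gene_window, "snp_window": config.snp_window,
            "n_perm": config.n_perm, "z_crit": config.z_crit,
        },
        "se_counts": {
            "before": {"SE": len(part_b.superenhancers), "TE": len(part_b.typical)},
            "after": {"SE": len(part_a.superenhancers), "TE": len(part_a.typical)},
        },
        "pattern_census": census,
        "transitions": _fate_census(trans),
        "enrichment": enrich_rows,
        "n_se_near_snp": int(sum(snp_flags)),
        "expression": {
            "n_genes_input": int(counts.shape[0]),
            "n_genes_retained": len(retained),
            "n_significant": int(de_df["significant"].sum()),
            "n_highly_expressed": int(de_df["highly_expressed"].sum()),
            "kruskal_p_regulatory_effect": (
                comparison.kw_p if comparison is not None else None
            ),
        },
        "gc": gc_report,
        "gsea": (
            {
                "es": gsea_res.es, "nes": gsea_res.nes,
                "p_perm": gsea_res.p_perm,
                "n_leading_edge": len(gsea_res.leading_edge),
            }
            if gsea_res is not None
            else None
        ),
        "recovery": recovery,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("report written to %s", outdir / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _patterns_table(patterns) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": sp.se.region.chrom, "start": sp.se.region.start,
             "end": sp.se.region.end, "condition": sp.condition,
             "pattern": sp.pattern.value, "n_persistent": sp.n_persistent,
             "n_primary": sp.n_primary, "n_secondary": sp.n_secondary}
            for sp in patterns
        ]
    )


def _transitions_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.before_se.se.region.chrom,
                "start": r.before_se.se.region.start,
                "end": r.before_se.se.region.end,
                "before_pattern": r.before_se.pattern.value,
                "after_patterns": ",".join(a.pattern.value for a in r.after_ses) or ".",
                "fate": r.fate.value,
                "multi_mapping": r.multi_mapping,
            }
        )
    return pd.DataFrame(rows)


def _fate_census(records) -> dict:
    out: dict[str, int] = {}
    for r in records:
        key = r.before_se.pattern.value + "->" + (
            ",".join(sorted({a.pattern.value for a in r.after_ses})) or "lost"
        )
        out[key] = out.get(key, 0) + 1
    return out


def _gc_by_pattern(bundle, patterns_a, part_a) -> dict:
    """Per-pattern mean GC of after-condition SEs vs typical enhancers,
    with a rank test of SE3 against TE (the planted contrast)."""
    from pyfaidx import Fasta

    from .expression_stats import kruskal_dunn, region_gc

    fasta = Fasta(str(bundle.genome_fasta))
    by_pattern: dict[str, list[float]] = {}
    for sp in patterns_a:
        by_pattern.setdefault(sp.pattern.value, []).append(
            region_gc(sp.se.region, fasta)
        )
    te_gc = [region_gc(r.region, fasta) for r in part_a.typical]
    if te_gc:
        by_pattern["TE"] = te_gc
    report = {k: {"mean_gc": float(np.mean(v)), "n": len(v)}
              for k, v in sorted(by_pattern.items())}
    if "SE3" in by_pattern and "TE" in by_pattern and len(by_pattern["SE3"]) >= 2:
        comp = kruskal_dunn({"SE3": by_pattern["SE3"], "TE": by_pattern["TE"]})
        report["SE3_vs_TE_p"] = comp.kw_p
    return report


def _de_recall(truth, de_df: pd.DataFrame) -> float:
    truly_de = {g["name"] for g in truth.genes if g["is_de"]}
    if not truly_de:
        return 1.0
    called = set(de_df.loc[de_df["significant"], "gene"])
    return len(truly_de & called) / len(truly_de)
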