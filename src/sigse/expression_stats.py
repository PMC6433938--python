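"""Expression-side statistics.

Covers CPM filtering of a counts matrix, a transparent two-group
differential-expression stand-in (Welch t on log2(CPM + 0.5)) with the
study thresholds (p < 0.05 and |log2FC| >= 1 for "significantly regulated";
average log2 expression > 5 for "highly expressed"), Kruskal-Wallis with
Dunn's tie-corrected post-hoc pairwise z tests under Bonferroni correction,
Pearson density correlations with Bonferroni, and GC content of genomic
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DE_P_THRESHOLD = 0.05
DE_LFC_THRESHOLD = 1.0
HIGH_EXPR_THRESHOLD = 5.0
CPM_THRESHOLD = 0.5
CPM_MIN_SAMPLES = 2
LOG2_PSEUDOCOUNT = 0.5
DENSITY_FLOOR_RPM_BP = 0.001  # floor before log2 of per-region densities


@dataclass(frozen=True, slots=True)
class DERecord:
    gene: str
    log2fc: float
    ave_expr: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < DE_P_THRESHOLD and abs(self.log2fc) >= DE_LFC_THRESHOLD

    @property
    def highly_expressed(self) -> bool:
        return self.ave_expr > HIGH_EXPR_THRESHOLD


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise z with Bonferroni."""

    groups: dict[str, np.ndarray]
    kw_stat: float
    kw_p: float
    pairwise: dict[tuple[str, str], tuple[float, float, float]]  # z, p_raw, p_adj


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column. Zero-total samples are an error."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts / totals * 1e6


def cpm_filter(
    counts: pd.DataFrame,
    threshold: float = CPM_THRESHOLD,
    min_samples: int = CPM_MIN_SAMPLES,
) -> tuple[list[str], pd.DataFrame]:
    """Retain genes with CPM > *threshold* in at least *min_samples* samples.

    Returns (retained gene list, CPM matrix restricted to retained genes).
    CPM uses the pre-filter library sizes.
    """
    cpm_mat = cpm(counts)
    keep = (cpm_mat > threshold).sum(axis=1) >= min_samples
    retained = list(counts.index[keep])
    return retained, cpm_mat.loc[keep]


def simple_de(
    cpm_mat: pd.DataFrame, groups: Mapping[str, str], contrast: tuple[str, str]
) -> list[DERecord]:
    """Two-group differential expression on log2(CPM + 0.5).

    *groups* maps sample name -> group label; *contrast* is
    (treated, reference): log2fc = mean(treated) − mean(reference).
    A transparent stand-in for a moderated linear-model fit; a precomputed
    DE table can be flagged with :func:`flag_de_table` instead.
    """
    treated, reference = contrast
    cols_t = [s for s, g in groups.items() if g == treated]
    cols_r = [s for s, g in groups.items() if g == reference]
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError("need >=2 samples per group")
    log_mat = np.log2(cpm_mat + LOG2_PSEUDOCOUNT)
    a = log_mat[cols_t].to_numpy()
    b = log_mat[cols_r].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ave = log_mat[cols_t + cols_r].to_numpy().mean(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant-count genes trigger scipy's near-identical-data warning;
        # their NaN p-values are mapped to 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    return [
        DERecord(g, float(lfc[i]), float(ave[i]), float(p[i]))
        for i, g in enumerate(cpm_mat.index)
    ]


def flag_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute significance flags from a supplied DE table.

    Expects columns gene, log2fc, ave_expr, p_value; adds ``significant``
    (p < 0.05 and |log2fc| >= 1) and ``highly_expressed`` (ave_expr > 5).
    """
    out = table.copy()
    out["significant"] = (out["p_value"] < DE_P_THRESHOLD) & (
        out["log2fc"].abs() >= DE_LFC_THRESHOLD
    )
    out["highly_expressed"] = out["ave_expr"] > HIGH_EXPR_THRESHOLD
    return out


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z tests.

    Ties get average ranks; the Dunn variance uses the tie-corrected form
    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/n_i + 1/n_j))
    with ΣT = Σ(t³ − t) over tie groups. Pairwise two-sided normal p-values
    are Bonferroni-adjusted over all k(k−1)/2 pairs. If every pooled value
    is identical, kw_p and all adjusted p are 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    pooled = np.concatenate([arrays[k] for k in labels])
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        pairwise = {
            pair: (0.0, 1.0, 1.0) for pair in combinations(labels, 2)
        }
        return GroupComparison(arrays, 0.0, 1.0, pairwise)

    kw_stat, kw_p = stats.kruskal(*(arrays[k] for k in labels))

    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in labels:
        n = arrays[k].size
        mean_ranks[k] = float(ranks[pos : pos + n].mean())
        sizes[k] = n
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    pairwise: dict[tuple[str, str], tuple[float, float, float]] = {}
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        pairwise[(a, b)] = (float(z), float(p_raw), float(min(1.0, p_raw * m)))
    return GroupComparison(arrays, float(kw_stat), float(kw_p), pairwise)


def density_correlation(
    pairs: Sequence[tuple[str, Sequence[float], Sequence[float]]],
    n_tests: int | None = None,
    floor: float = DENSITY_FLOOR_RPM_BP,
) -> pd.DataFrame:
    """Pearson correlation between paired per-region log2(rpm/bp) vectors.

    Each entry of *pairs* is (label, densities_x, densities_y) in rpm/bp;
    densities are floored at *floor* before the log2 transform so zero
    densities stay finite. Raw p-values come from the t distribution;
    the Bonferroni column multiplies by *n_tests* (default: len(pairs)).
    Zero-variance vectors yield NaN r with ``defined=False``.
    """
    if n_tests is None:
        n_tests = len(pairs)
    rows = []
    for label, xs, ys in pairs:
        x = np.log2(np.maximum(np.asarray(xs, dtype=float), floor))
        y = np.log2(np.maximum(np.asarray(ys, dtype=float), floor))
        if x.size != y.size or x.size < 3:
            raise ValueError(f"pair {label!r}: vectors must share length >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {"label": label, "r": np.nan, "p": np.nan, "p_bonferroni": np.nan,
                 "n": x.size, "defined": False}
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "label": label,
                "r": float(r),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * n_tests)),
                "n": x.size,
                "defined": True,
            }
        )
    return pd.DataFrame(rows)


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence; N (and other ambiguity codes) excluded
    from the denominator. All-N sequences raise ValueError."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / acgt


def region_gc(region, fasta) -> float:
    """GC content of *region* from an indexed FASTA (pyfaidx.Fasta)."""
    seq = fasta[region.chrom][region.start : region.end].seq
    return gc_content(seq)
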