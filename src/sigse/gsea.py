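"""Pre-ranked gene-set enrichment: weighted running-sum statistic.

Walking a ranked gene list from top to bottom, gene-set members ("hits")
increment the running sum by |score|^p normalised over all hits, and
non-members decrement it by 1/(N − N_hits). The enrichment score (ES) is
the signed value of the running sum at its point of maximal absolute
deviation from zero. Significance comes from gene-tag permutation (random
same-size subsets of the ranking), the only null available in pre-ranked
mode. p = 1 is the classic weighted default; p = 0 gives the
Kolmogorov-Smirnov-like unweighted statistic whose running sum telescopes
back to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gene_linking import GeneSet

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1_000


@dataclass(frozen=True, slots=True)
class RankedList:
    """Ordered unique gene symbols with non-increasing ranking scores."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, float]]) -> "RankedList":
        ordered = sorted(pairs, key=lambda gv: -gv[1])
        return cls(tuple(g for g, _ in ordered), tuple(v for _, v in ordered))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True, slots=True)
class GseaResult:
    es: float
    nes: float
    p_perm: float
    p_perm_one_sided: float
    leading_edge: tuple[str, ...]
    trailing_edge_flag: bool
    peak_index: int
    n_perm: int
    seed: int
    weight: float


def _running_sum(
    hit_mask: np.ndarray, scores: np.ndarray, weight: float
) -> np.ndarray:
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(scores) ** weight
    hit_total = float(w[hit_mask].sum())
    steps = np.where(
        hit_mask,
        (w / hit_total if hit_total > 0 else np.full(n, 1.0 / n_hits)),
        -1.0 / (n - n_hits),
    )
    if hit_total == 0:  # all-hit scores zero at weight > 0: fall back to equal mass
        steps = np.where(hit_mask, 1.0 / n_hits, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | Sequence[str], weight: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray, int]:
    """ES, full running sum, and the 0-based rank index of its extremum.

    The extremum is the first index attaining the maximal |running sum|.
    The gene set must hit the ranking without covering it entirely.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hit_mask = np.array([g in members for g in ranked.genes], dtype=bool)
    running = _running_sum(hit_mask, np.asarray(ranked.scores, dtype=float), weight)
    es, peak = _es_from_running(running)
    return es, running, peak


def leading_edge(
    running: np.ndarray,
    peak_index: int,
    ranked: RankedList,
    gene_set: GeneSet | Sequence[str],
) -> tuple[tuple[str, ...], bool]:
    """Gene-set members at ranks <= peak for a positive ES.

    For a non-positive ES the trailing-edge analog (members at ranks >=
    peak) is returned with the flag set.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    es = float(running[peak_index])
    if es > 0:
        genes = tuple(g for g in ranked.genes[: peak_index + 1] if g in members)
        return genes, False
    genes = tuple(g for g in ranked.genes[peak_index:] if g in members)
    return genes, True


def gsea_test(
    ranked: RankedList,
    gene_set: GeneSet | Sequence[str],
    weight: float = DEFAULT_WEIGHT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> GseaResult:
    """Permutation GSEA on a pre-ranked list.

    Null: *n_perm* random gene subsets of the same size drawn from the
    ranking (gene-tag permutation). Two-sided p compares |ES|; the
    one-sided variant counts permutations at least as extreme in the
    observed direction. NES divides ES by the mean |null ES| of matching
    sign (NaN if no null ES shares the sign). Deterministic given *seed*.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    scores = np.asarray(ranked.scores, dtype=float)
    hit_mask = np.array([g in members for g in ranked.genes], dtype=bool)
    running = _running_sum(hit_mask, scores, weight)
    es, peak = _es_from_running(running)
    n, n_hits = hit_mask.size, int(hit_mask.sum())

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    perm_mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        perm_mask[:] = False
        perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
        null_es[i] = _es_from_running(_running_sum(perm_mask, scores, weight))[0]

    p_two = (1 + int(np.sum(np.abs(null_es) >= abs(es)))) / (1 + n_perm)
    if es >= 0:
        p_one = (1 + int(np.sum(null_es >= es))) / (1 + n_perm)
        same_sign = null_es[null_es > 0]
    else:
        p_one = (1 + int(np.sum(null_es <= es))) / (1 + n_perm)
        same_sign = null_es[null_es < 0]
    nes = es / float(np.abs(same_sign).mean()) if same_sign.size else float("nan")

    edge, trailing = leading_edge(running, peak, ranked, gene_set)
    return GseaResult(
        es=es,
        nes=float(nes),
        p_perm=p_two,
        p_perm_one_sided=p_one,
        leading_edge=edge,
        trailing_edge_flag=trailing,
        peak_index=peak,
        n_perm=n_perm,
        seed=seed,
        weight=weight,
    )
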