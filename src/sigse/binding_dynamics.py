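"""Classify TF binding dynamics across a stimulation contrast.

Sites present only before stimulation are *primary*, sites present in both
conditions (>=1 bp overlap between the condition peak sets) are
*persistent*, and sites present only after stimulation are *secondary*.
Super-enhancers are then classified by the dynamics of their overlapping
sites: after-stimulation SEs become SE1 (persistent only), SE2 (persistent
and secondary) or SE3 (secondary only); before-stimulation SEs become SE4
(persistent only), SE5 (persistent and primary) or SE6 (primary only).
An SE overlapping no labelled site is UNBOUND (possible when SEs are called
from a different mark than the labelled TF).

Persistent sites are represented in each condition by that condition's own
peak coordinates, with partner links to the other condition; a peak
overlapping several partners yields a single persistent label carrying all
of them, preserving the partition identity |PRIMARY| + |PERSISTENT(before)|
= |before peaks|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .intervals import Peak
from .se_detection import SEPartition, StitchedEnhancer


class SiteLabel(str, Enum):
    PRIMARY = "PRIMARY"          # before only
    PERSISTENT = "PERSISTENT"    # both conditions
    SECONDARY = "SECONDARY"      # after only


class Pattern(str, Enum):
    SE1 = "SE1"  # after: persistent only
    SE2 = "SE2"  # after: persistent + secondary
    SE3 = "SE3"  # after: secondary only
    SE4 = "SE4"  # before: persistent only
    SE5 = "SE5"  # before: persistent + primary
    SE6 = "SE6"  # before: primary only
    UNBOUND = "UNBOUND"


class Fate(str, Enum):
    PERSISTS_AS = "persists_as"
    RECLASSIFIED_AS = "reclassified_as"
    LOST = "lost"


#: Before-pattern -> after-patterns that count as "the same SE persisting":
#: a persistent-only SE staying persistent-only (SE4 -> SE1), a mixed SE
#: keeping its persistent core (SE5 -> SE1 or SE2), and a primary-only SE
#: whose region stays SE through purely condition-specific binding
#: (SE6 -> SE3 class).
_PERSISTENCE_MAP: dict[Pattern, frozenset[Pattern]] = {
    Pattern.SE4: frozenset({Pattern.SE1}),
    Pattern.SE5: frozenset({Pattern.SE1, Pattern.SE2}),
    Pattern.SE6: frozenset({Pattern.SE3}),
}


@dataclass(frozen=True, slots=True)
class DynamicsLabel:
    """One labelled binding site in one condition."""

    site: Peak
    label: SiteLabel
    partners: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        if (self.label is SiteLabel.PERSISTENT) != bool(self.partners):
            raise ValueError("partners present iff label is PERSISTENT")


@dataclass(frozen=True, slots=True)
class SEPattern:
    """An SE's dynamics pattern in one condition, with overlap counts."""

    se: StitchedEnhancer
    condition: str  # "before" | "after"
    pattern: Pattern
    n_persistent: int = 0
    n_primary: int = 0
    n_secondary: int = 0


@dataclass(frozen=True, slots=True)
class TransitionRecord:
    """Fate of one before-stimulation SE across the contrast."""

    before_se: SEPattern
    after_ses: tuple[SEPattern, ...]
    fate: Fate
    multi_mapping: bool = False


def label_sites(
    before_peaks: Sequence[Peak], after_peaks: Sequence[Peak]
) -> tuple[list[DynamicsLabel], list[DynamicsLabel]]:
    """Label both peak sets by cross-condition >=1 bp overlap.

    Returns (labels_before, labels_after), each parallel to its input.
    """
    partners_b = _overlap_partners(before_peaks, after_peaks)
    partners_a = _overlap_partners(after_peaks, before_peaks)
    labels_before = [
        DynamicsLabel(p, SiteLabel.PERSISTENT, tuple(ps))
        if ps
        else DynamicsLabel(p, SiteLabel.PRIMARY)
        for p, ps in zip(before_peaks, partners_b)
    ]
    labels_after = [
        DynamicsLabel(p, SiteLabel.PERSISTENT, tuple(ps))
        if ps
        else DynamicsLabel(p, SiteLabel.SECONDARY)
        for p, ps in zip(after_peaks, partners_a)
    ]
    return labels_before, labels_after


def _overlap_partners(
    query: Sequence[Peak], subject: Sequence[Peak]
) -> list[list[Peak]]:
    by_chrom: dict[str, list[tuple[int, int, Peak]]] = {}
    for p in subject:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, p))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[Peak]]] = {}
    for chrom, triples in by_chrom.items():
        triples.sort(key=lambda t: (t[0], t[1]))
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        index[chrom] = (starts, ends, np.maximum.accumulate(ends), [t[2] for t in triples])
    out: list[list[Peak]] = []
    for q in query:
        entry = index.get(q.chrom)
        hits: list[Peak] = []
        if entry is not None:
            starts, ends, prefix_max_end, peaks = entry
            j = int(np.searchsorted(starts, q.end, side="left"))
            for k in range(j - 1, -1, -1):
                # nothing at or before k can overlap once the running max end
                # drops to q.start or below
                if prefix_max_end[k] <= q.start:
                    break
                if ends[k] > q.start:
                    hits.append(peaks[k])
        hits.reverse()
        out.append(hits)
    return out


def classify_se(
    se: StitchedEnhancer, labels: Sequence[DynamicsLabel], condition: str
) -> SEPattern:
    """Classify one SE from the labelled sites of its own condition."""
    if condition not in ("before", "after"):
        raise ValueError("condition must be 'before' or 'after'")
    counts = Counter()
    for lab in labels:
        iv = lab.site.interval
        if (
            iv.chrom == se.region.chrom
            and iv.start < se.region.end
            and se.region.start < iv.end
        ):
            counts[lab.label] += 1
    n_persistent = counts[SiteLabel.PERSISTENT]
    n_primary = counts[SiteLabel.PRIMARY]
    n_secondary = counts[SiteLabel.SECONDARY]
    if condition == "after":
        if n_persistent and n_secondary:
            pattern = Pattern.SE2
        elif n_persistent:
            pattern = Pattern.SE1
        elif n_secondary:
            pattern = Pattern.SE3
        else:
            pattern = Pattern.UNBOUND
    else:
        if n_persistent and n_primary:
            pattern = Pattern.SE5
        elif n_persistent:
            pattern = Pattern.SE4
        elif n_primary:
            pattern = Pattern.SE6
        else:
            pattern = Pattern.UNBOUND
    return SEPattern(se, condition, pattern, n_persistent, n_primary, n_secondary)


def classify_partition(
    partition: SEPartition, labels: Sequence[DynamicsLabel], condition: str
) -> list[SEPattern]:
    """Classify every super-enhancer of a partition."""
    return [classify_se(se, labels, condition) for se in partition.superenhancers]


def transitions(
    before_patterns: Sequence[SEPattern], after_patterns: Sequence[SEPattern]
) -> list[TransitionRecord]:
    """Track each before-stimulation SE to its overlapping after-SEs.

    Fate is LOST when no after-SE overlaps; PERSISTS_AS when every
    overlapping after-pattern is persistence-compatible with the before
    pattern (SE4 -> SE1, SE5 -> SE1/SE2, SE6 -> SE3); otherwise
    RECLASSIFIED_AS. A before-SE overlapping more than one after-SE is
    flagged multi-mapping and all hits are recorded.
    """
    records: list[TransitionRecord] = []
    for bp in before_patterns:
        hits = tuple(
            ap
            for ap in after_patterns
            if ap.se.region.chrom == bp.se.region.chrom
            and ap.se.region.start < bp.se.region.end
            and bp.se.region.start < ap.se.region.end
        )
        if not hits:
            records.append(TransitionRecord(bp, (), Fate.LOST))
            continue
        allowed = _PERSISTENCE_MAP.get(bp.pattern, frozenset())
        fate = (
            Fate.PERSISTS_AS
            if all(ap.pattern in allowed for ap in hits)
            else Fate.RECLASSIFIED_AS
        )
        records.append(TransitionRecord(bp, hits, fate, multi_mapping=len(hits) > 1))
    return records


def pattern_census(patterns: Sequence[SEPattern]) -> dict[str, int]:
    """Counts per pattern; values sum to the number of inputs."""
    census = {p.value: 0 for p in Pattern}
    for sp in patterns:
        census[sp.pattern.value] += 1
    return census
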