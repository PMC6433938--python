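"""Core genomic-interval data model, standard-format I/O and set operations.

All coordinates are 0-based half-open (BED convention). GTF input (1-based,
closed) is converted on read. Overlap requires at least one shared base:
half-open adjacency is *not* overlap, matching the ``bedtools intersect``
default. Strand is carried but ignored by every overlap/merge operation,
because enhancer calls are unstranded.

Chromosome names are matched as exact strings; no "chr" normalisation is
attempted. :func:`warn_chrom_mismatch` reports names present in only one of
two inputs so that data errors surface instead of silently vanishing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "Genome",
    "GeneModel",
    "CoverageTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_chrom_sizes",
    "read_genes",
    "read_gtf_genes",
    "read_gene_table",
    "merge_overlapping",
    "overlap_any",
    "remove_blacklisted",
    "warn_chrom_mismatch",
]


class BedParseError(ValueError):
    """Raised when a BED-family line cannot be parsed; names the line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Invariants: ``0 <= start < end``. Intervals sort by (chrom, start, end).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def width(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, slots=True)
class Peak:
    """A called peak: an interval plus name, score and optional summit."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak "
                f"{self.interval} of width {self.interval.width}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene body with a strand-derived transcription start site.

    TSS is ``region.start`` on the + strand and ``region.end - 1`` on the
    − strand (the last covered base of the half-open interval).
    """

    name: str
    region: GenomicInterval

    @property
    def tss(self) -> int:
        if self.region.strand == "-":
            return self.region.end - 1
        return self.region.start


@dataclass
class Genome:
    """Chromosome sizes plus blacklist regions excluded from all analyses."""

    chrom_sizes: dict[str, int]
    blacklist: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.blacklist:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"blacklist interval {iv} on unknown chromosome")
            if iv.end > size:
                raise ValueError(
                    f"blacklist interval {iv} exceeds chromosome length {size}"
                )

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BED_DIALECTS = ("bed3", "bed6", "narrowPeak")


def read_bed(path: str | Path, dialect: str = "bed6") -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into peaks, in file order.

    Coordinates are parsed as 0-based half-open. For the narrowPeak dialect
    the 10th column is parsed as the summit offset (``-1`` meaning absent).
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}; expected {_BED_DIALECTS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad score: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            summit: int | None = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise BedParseError(
                        f"{path}:{lineno}: narrowPeak requires 10 fields"
                    )
                summit = int(fields[9])
                if summit < 0:
                    summit = None
                score = float(fields[6])  # signalValue column
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(iv, name=name, score=score, summit_offset=summit))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval | Peak],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as sorted, tab-separated, newline-terminated BED."""
    rows = []
    for i, item in enumerate(intervals):
        iv = item.interval if isinstance(item, Peak) else item
        name = (
            names[i]
            if names is not None
            else (item.name if isinstance(item, Peak) else ".")
        )
        score = (
            scores[i]
            if scores is not None
            else (item.score if isinstance(item, Peak) else 0.0)
        )
        rows.append((iv.chrom, iv.start, iv.end, name, score, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


class CoverageTrack:
    """Piecewise-constant per-base coverage, as read from a 4-column bedGraph.

    Stored per chromosome as sorted, non-overlapping (starts, ends, values)
    arrays. Bases not covered by any bedGraph record have coverage 0.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping bedGraph records on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def region_sum(self, region: GenomicInterval) -> float:
        """Sum of per-base coverage over *region*; missing bases count 0."""
        entry = self._data.get(region.chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        i0 = int(np.searchsorted(ends, region.start, side="right"))
        i1 = int(np.searchsorted(starts, region.end, side="left"))
        if i1 <= i0:
            return 0.0
        s = np.maximum(starts[i0:i1], region.start)
        e = np.minimum(ends[i0:i1], region.end)
        return float(np.sum((e - s) * values[i0:i1]))

    def total(self) -> float:
        """Genome-wide sum of base-level coverage."""
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self._data.values())
        )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, start, end, value = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    data = {
        chrom: (
            np.array([r[0] for r in recs]),
            np.array([r[1] for r in recs]),
            np.array([r[2] for r in recs]),
        )
        for chrom, recs in per_chrom.items()
    }
    return CoverageTrack(data)


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene records (feature type ``gene``) from a GTF file.

    GTF coordinates are 1-based closed and are converted to 0-based
    half-open on read. The gene symbol is taken from the ``gene_name``
    attribute, falling back to ``gene_id``.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom = fields[0]
            start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
            end = int(fields[4])
            strand = fields[6] if fields[6] in "+-" else "."
            attrs = fields[8]
            name = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "gene_id")
            if name is None:
                raise BedParseError(f"{path}:{lineno}: gene without gene_name/gene_id")
            genes.append(GeneModel(name, GenomicInterval(chrom, start, end, strand)))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk[len(key) :].strip().strip('"')
    return None


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a 5-column TSV gene annotation: name, chrom, start, end, strand.

    Coordinates are 0-based half-open (the package's own writers produce
    this format). A header line starting with ``name`` is tolerated.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("name\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}:{lineno}: expected 5 columns")
            name, chrom, start, end, strand = fields[:5]
            genes.append(
                GeneModel(
                    name,
                    GenomicInterval(
                        chrom, int(start), int(end), strand if strand in "+-" else "."
                    ),
                )
            )
    return genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: ``.gtf``/``.gff`` via GTF reader, else 5-col TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return read_gtf_genes(path)
    return read_gene_table(path)


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------


def overlap_any(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (same chromosome)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_overlapping(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals whose gap is at most *max_gap* bp.

    Returns the minimal set of disjoint intervals, sorted by
    (chrom, start, end), such that any two inputs with gap <= max_gap fall
    into the same output (transitive closure). ``max_gap=0`` merges only
    overlapping or book-ended intervals.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= max_gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def merge_with_members(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[tuple[GenomicInterval, list[int]]]:
    """Like :func:`merge_overlapping` but also returns input indices per cluster."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    order = sorted(range(len(intervals)), key=lambda i: intervals[i].sort_key())
    out: list[tuple[GenomicInterval, list[int]]] = []
    for idx in order:
        iv = intervals[idx]
        if out and iv.chrom == out[-1][0].chrom and iv.start - out[-1][0].end <= max_gap:
            prev, members = out[-1]
            new_end = max(prev.end, iv.end)
            out[-1] = (GenomicInterval(prev.chrom, prev.start, new_end), members + [idx])
        else:
            out.append((GenomicInterval(iv.chrom, iv.start, iv.end), [idx]))
    return out


class _IntervalIndex:
    """Sorted per-chromosome index supporting 'overlaps anything?' queries.

    Uses the sorted-starts + prefix-max-of-ends trick: an interval
    [s, e) overlaps some indexed interval iff among indexed intervals with
    start < e there is one with end > s.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in per.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._index[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._index.get(iv.chrom)
        if entry is None:
            return False
        starts, prefix_max_end = entry
        j = int(np.searchsorted(starts, iv.end, side="left"))
        return j > 0 and prefix_max_end[j - 1] > iv.start

    def overlaps_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        entry = self._index.get(chrom)
        if entry is None:
            return np.zeros(len(starts), dtype=bool)
        idx_starts, prefix_max_end = entry
        j = np.searchsorted(idx_starts, ends, side="left")
        hit = j > 0
        hit[hit] = prefix_max_end[j[hit] - 1] > starts[hit]
        return hit


def remove_blacklisted(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Drop every peak overlapping (>=1 bp) any blacklist interval.

    Input order is preserved. Idempotent by construction.
    """
    if not blacklist:
        return list(peaks)
    index = _IntervalIndex(blacklist)
    return [p for p in peaks if not index.overlaps(p.interval)]


def warn_chrom_mismatch(
    left: Iterable[str], right: Iterable[str], context: str = ""
) -> set[str]:
    """Warn about chromosome names present in only one of two inputs."""
    only = set(left) ^ set(right)
    if only:
        warnings.warn(
            f"chromosome names present in only one input{' (' + context + ')' if context else ''}: "
            f"{sorted(only)}",
            stacklevel=2,
        )
    return only


def iter_peak_intervals(peaks: Iterable[Peak]) -> Iterator[GenomicInterval]:
    for p in peaks:
        yield p.interval
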