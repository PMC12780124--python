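"""Pairwise contact expansion and contact-level statistics.

A concatemer read whose n segments are aligned independently represents all
C(n, 2) pairwise chromatin interactions among them — e.g. 17 aligned segments
expand to 136 pairs, the information content of 272 short paired-end reads.
This module performs that expansion, emits mock Illumina-like paired-end
records for tools that consume paired reads (scaffolders, pair-based
pipelines), filters pairs on mapping quality, marks PCR duplicates and
computes distance-decay and segment-distribution statistics.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import reverse_complement

MAPQ_CUTOFFS = (1, 10, 20, 30, 60)


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned (or unmapped) segment of a concatemer read.

    ``chrom is None`` marks an unmapped segment; its coordinates, strand and
    MAPQ are then meaningless and treated as absent.  ``haplotype_tag`` mirrors
    an HP-style integer tag (1 or 2) when the segment overlaps phased variants.
    """

    read_id: str
    segment_index: int
    chrom: str | None
    ref_start: int
    ref_end: int
    strand: str = "+"
    mapq: int = 0
    haplotype_tag: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.chrom is not None:
            if self.ref_start >= self.ref_end:
                raise ValueError(
                    f"{self.read_id}[{self.segment_index}]: empty reference interval")
            if self.strand not in "+-":
                raise ValueError(f"invalid strand {self.strand!r}")
        if self.haplotype_tag not in (None, 1, 2):
            raise ValueError(f"haplotype tag must be 1, 2 or None")

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def position(self) -> int:
        """Representative contact position: the 5'-most mapped base (strand-aware)."""
        return self.ref_start if self.strand == "+" else self.ref_end - 1


@dataclass(frozen=True)
class ContactPair:
    """One pairwise interaction between two segments of the same read.

    Mates of a fully mapped pair are stored in upper-triangle order
    (chrom1 <= chrom2 by sort order, pos1 <= pos2 within a chromosome), the
    convention of the pairs text format.  Pairs with an unmapped mate keep
    segment-index order and are removed by :func:`filter_pairs`.
    """

    read_id: str
    index1: int
    index2: int
    chrom1: str | None
    pos1: int
    strand1: str
    mapq1: int
    chrom2: str | None
    pos2: int
    strand2: str
    mapq2: int

    @property
    def both_mapped(self) -> bool:
        return self.chrom1 is not None and self.chrom2 is not None

    @property
    def pair_class(self) -> str | None:
        if not self.both_mapped:
            return None
        return "cis" if self.chrom1 == self.chrom2 else "trans"

    @property
    def is_cis(self) -> bool:
        return self.pair_class == "cis"

    @property
    def distance(self) -> int | None:
        """Genomic separation of the two mates; defined for cis pairs only."""
        if self.pair_class != "cis":
            return None
        return abs(self.pos2 - self.pos1)


@dataclass(frozen=True)
class MateRecord:
    """One mate of a mock paired-end template."""

    chrom: str | None
    pos: int
    strand: str
    mapq: int
    sequence: str | None
    is_first: bool


@dataclass(frozen=True)
class MockPairedRecord:
    template_id: str
    mate1: MateRecord
    mate2: MateRecord


def _pair_from_segments(a: AlignedSegment, b: AlignedSegment) -> ContactPair:
    def key(seg: AlignedSegment):
        return (seg.chrom, seg.position)

    if a.is_mapped and b.is_mapped and key(b) < key(a):
        a, b = b, a
    return ContactPair(
        read_id=a.read_id,
        index1=min(a.segment_index, b.segment_index),
        index2=max(a.segment_index, b.segment_index),
        chrom1=a.chrom, pos1=a.position if a.is_mapped else -1,
        strand1=a.strand if a.is_mapped else ".",
        mapq1=a.mapq if a.is_mapped else -1,
        chrom2=b.chrom, pos2=b.position if b.is_mapped else -1,
        strand2=b.strand if b.is_mapped else ".",
        mapq2=b.mapq if b.is_mapped else -1,
    )


def expand_pairwise(segments: Sequence[AlignedSegment]) -> list[ContactPair]:
    """All C(n, 2) pairwise contacts among the segments of one read.

    Unmapped segments participate too (their pairs carry the unmapped mate and
    are dropped later by :func:`filter_pairs`), so rejection tallies remain
    observable downstream.
    """
    if not segments:
        return []
    read_ids = {s.read_id for s in segments}
    if len(read_ids) != 1:
        raise ValueError(f"segments from multiple reads passed: {sorted(read_ids)}")
    ordered = sorted(segments, key=lambda s: s.segment_index)
    return [_pair_from_segments(a, b) for a, b in itertools.combinations(ordered, 2)]


def expand_reads(reads: Mapping[str, Sequence[AlignedSegment]]) -> list[ContactPair]:
    """Expand every read of a read_id -> segments mapping, in sorted read order."""
    pairs: list[ContactPair] = []
    for read_id in sorted(reads):
        pairs.extend(expand_pairwise(reads[read_id]))
    return pairs


def emit_mock_pairs(pairs: Sequence[ContactPair],
                    segments: Sequence[AlignedSegment],
                    mate_length: int = 150) -> list[MockPairedRecord]:
    """Mock Illumina-like paired-end records, one template per contact pair.

    Mate 1 takes up to ``mate_length`` bases from its segment's 5' end; mate 2
    takes the same slice of its segment but is emitted reverse-complemented,
    giving the conventional FR orientation.  Mate coordinates are the source
    segments' mapping coordinates, so the records are directly usable by
    pair-consuming scaffolders.  Output count is always ``2 * len(pairs)``.
    """
    if mate_length < 1:
        raise ValueError(f"mate_length must be >= 1, got {mate_length}")
    by_index: dict[tuple[str, int], AlignedSegment] = {
        (s.read_id, s.segment_index): s for s in segments}
    records = []
    for pair in pairs:
        seg1 = by_index.get((pair.read_id, pair.index1))
        seg2 = by_index.get((pair.read_id, pair.index2))
        if seg1 is None or seg2 is None:
            raise ValueError(
                f"pair {pair.read_id}:{pair.index1}-{pair.index2} "
                "references segments not present in the segment list")
        template_id = f"{pair.read_id}:{pair.index1}-{pair.index2}"

        def mate(seg: AlignedSegment, first: bool) -> MateRecord:
            seq = None
            if seg.sequence is not None:
                seq = seg.sequence[:mate_length]
                if not first:
                    seq = reverse_complement(seq)
            return MateRecord(chrom=seg.chrom,
                              pos=seg.position if seg.is_mapped else -1,
                              strand=seg.strand if seg.is_mapped else ".",
                              mapq=seg.mapq if seg.is_mapped else 0,
                              sequence=seq, is_first=first)

        records.append(MockPairedRecord(template_id, mate(seg1, True), mate(seg2, False)))
    return records


@dataclass
class FilterTally:
    """Bookkeeping for :func:`filter_pairs`: input = retained + per-reason rejections."""

    total: int = 0
    retained: int = 0
    unmapped_mate: int = 0
    low_mapq: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"total": self.total, "retained": self.retained,
                "unmapped_mate": self.unmapped_mate, "low_mapq": self.low_mapq}


def filter_pairs(pairs: Iterable[ContactPair],
                 mapq_min: int = 1) -> tuple[list[ContactPair], FilterTally]:
    """Keep pairs with both mates mapped and ``min(mapq1, mapq2) >= mapq_min``.

    Rejection reasons are tallied with unmapped-mate taking precedence over
    low MAPQ, so the tally partitions the input exactly.
    """
    tally = FilterTally()
    retained = []
    for pair in pairs:
        tally.total += 1
        if not pair.both_mapped:
            tally.unmapped_mate += 1
        elif min(pair.mapq1, pair.mapq2) < mapq_min:
            tally.low_mapq += 1
        else:
            tally.retained += 1
            retained.append(pair)
    return retained, tally


@dataclass
class DuplicateReport:
    duplicates: set[str]
    n_reads: int

    @property
    def rate(self) -> float:
        return len(self.duplicates) / self.n_reads if self.n_reads else 0.0


def mark_duplicates(reads: Mapping[str, Sequence[AlignedSegment]]) -> DuplicateReport:
    """Flag PCR duplicates by identical alignment fingerprints.

    Reads whose segments (ordered by segment index) share an identical
    (chrom, ref_start, strand) fingerprint form one duplicate group; the
    first read id in sort order is kept as the representative, the rest are
    flagged.  The result is independent of input ordering and idempotent.
    """
    groups: dict[tuple, list[str]] = defaultdict(list)
    for read_id, segments in reads.items():
        fp = tuple(
            (s.chrom, s.ref_start if s.is_mapped else -1, s.strand if s.is_mapped else ".")
            for s in sorted(segments, key=lambda s: s.segment_index))
        groups[fp].append(read_id)
    dupes: set[str] = set()
    for members in groups.values():
        members.sort()
        dupes.update(members[1:])
    return DuplicateReport(duplicates=dupes, n_reads=len(reads))


def log_spaced_edges(min_distance: float = 1e3, max_distance: float = 3e8,
                     bins_per_decade: int = 8) -> np.ndarray:
    """Log-spaced distance bin edges in bp, the conventional decay binning."""
    n = int(np.ceil(np.log10(max_distance / min_distance) * bins_per_decade)) + 1
    return np.logspace(np.log10(min_distance), np.log10(max_distance), n)


def distance_histogram(pairs: Iterable[ContactPair],
                       edges: np.ndarray | Sequence[float] | None = None) -> pd.DataFrame:
    """Histogram of cis contact distances as percentages of all cis pairs.

    Trans pairs and pairs with unmapped mates are excluded from both numerator
    and denominator.  Percentages sum to 100 up to pairs falling outside the
    edge range; an all-trans input yields an empty (all-zero) histogram.
    """
    if edges is None:
        edges = log_spaced_edges()
    edges = np.asarray(edges, dtype=float)
    distances = np.array([p.distance for p in pairs if p.is_cis], dtype=float)
    counts, _ = np.histogram(distances, bins=edges)
    total = distances.size
    percent = counts / total * 100.0 if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts, "percent": percent})


def fit_decay_exponent(distances: Sequence[float] | np.ndarray,
                       d_min: float, d_max: float,
                       n_bins: int = 20) -> float:
    """Estimate the power-law decay exponent alpha with P(d) ~ d^-alpha.

    Log-log linear regression of binned count density against distance over
    ``[d_min, d_max]``; choose the range well inside the chromosome span so
    boundary truncation does not bias the slope.
    """
    d = np.asarray(distances, dtype=float)
    d = d[(d >= d_min) & (d <= d_max)]
    if d.size < 100:
        raise ValueError(f"too few distances in [{d_min}, {d_max}]: {d.size}")
    edges = np.logspace(np.log10(d_min), np.log10(d_max), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    slope, _ = np.polyfit(np.log(centers[keep]), np.log(counts[keep] / widths[keep]), 1)
    return -slope


def _lower_median(values: Sequence[float]) -> float:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def _mode(values: Sequence[float]) -> float:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def _summary(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(_lower_median(values)),
        "mode": float(_mode(values)),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


def segment_stats(reads: Mapping[str, Sequence[AlignedSegment]]) -> dict[str, dict[str, float]]:
    """Distribution summaries of segments-per-read and segment length.

    Median uses the lower-median convention for even counts; mode is the
    smallest most frequent value; sd is the sample standard deviation.
    """
    if not reads:
        raise ValueError("no reads supplied")
    per_read = [len(segs) for segs in reads.values()]
    lengths = [s.ref_end - s.ref_start if s.is_mapped else len(s.sequence or "")
               for segs in reads.values() for s in segs]
    lengths = [l for l in lengths if l > 0]
    out = {"segments_per_read": _summary(per_read)}
    if lengths:
        out["segment_length"] = _summary(lengths)
    return out
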