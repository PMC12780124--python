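"""Within-read haplotype concordance and phase imputation.

Segments of one concatemer read derive from a single chromosomal fiber, so
phased segments of a read overwhelmingly share one haplotype.  That makes a
conservative imputation rule possible: an unphased segment inherits a
haplotype when every phased segment of the same read on its chromosome within
a genomic window (default 30 Mbp) carries that same haplotype.  Original tags
are never modified, and only original tags serve as evidence (a single pass,
no chaining), so imputation can never contradict its own evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .contacts import AlignedSegment

DEFAULT_WINDOW = 30_000_000


@dataclass(frozen=True)
class PhasedReadSummary:
    """Per-read phasing bookkeeping.

    ``concordant`` is True when all phased same-chromosome segments of the
    read share a single haplotype; it is None for reads with fewer than two
    phased segments on any one chromosome (such reads are excluded from
    aggregate concordance denominators).  ``pair_concordance`` is the fraction
    of same-chromosome phased segment pairs that agree.
    """

    read_id: str
    n_segments: int
    n_phased_before: int
    n_phased_after: int
    concordant: bool | None
    pair_concordance: float | None
    n_pairs_same_chrom: int
    n_pairs_agreeing: int


def _phased_pairs(segments: Sequence[AlignedSegment]) -> tuple[int, int]:
    """(same-chromosome phased pairs, agreeing pairs) for one read."""
    phased = [s for s in segments if s.is_mapped and s.haplotype_tag is not None]
    total = agree = 0
    for a, b in itertools.combinations(phased, 2):
        if a.chrom != b.chrom:
            continue
        total += 1
        if a.haplotype_tag == b.haplotype_tag:
            agree += 1
    return total, agree


def read_concordance(segments: Sequence[AlignedSegment],
                     n_phased_after: int | None = None) -> PhasedReadSummary:
    """Haplotype concordance of the phased segments of one read."""
    read_ids = {s.read_id for s in segments}
    if len(read_ids) > 1:
        raise ValueError(f"segments from multiple reads: {sorted(read_ids)}")
    n_phased = sum(1 for s in segments if s.haplotype_tag is not None)
    total, agree = _phased_pairs(segments)
    return PhasedReadSummary(
        read_id=next(iter(read_ids)) if read_ids else "",
        n_segments=len(segments),
        n_phased_before=n_phased,
        n_phased_after=n_phased_after if n_phased_after is not None else n_phased,
        concordant=(agree == total) if total else None,
        pair_concordance=(agree / total) if total else None,
        n_pairs_same_chrom=total,
        n_pairs_agreeing=agree,
    )


@dataclass(frozen=True)
class ImputationEvent:
    read_id: str
    segment_index: int
    chrom: str
    position: int
    haplotype: int
    n_evidence: int


def impute_phase(segments: Sequence[AlignedSegment],
                 window: int = DEFAULT_WINDOW,
                 min_evidence: int = 1,
                 ) -> tuple[list[AlignedSegment], list[ImputationEvent]]:
    """Impute haplotype tags to unphased segments of one read.

    For each unphased mapped segment, the evidence set is the read's
    originally phased segments on the same chromosome whose representative
    positions lie within ``window`` bp (inclusive).  The segment is tagged only
    when the evidence set has at least ``min_evidence`` members and is
    unanimous; a conflict or an empty window leaves it untagged.  The pass is
    order-independent because only original tags are consulted.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    evidence = [s for s in segments if s.is_mapped and s.haplotype_tag is not None]
    out: list[AlignedSegment] = []
    events: list[ImputationEvent] = []
    for seg in segments:
        if not seg.is_mapped or seg.haplotype_tag is not None:
            out.append(seg)
            continue
        near = {e.haplotype_tag for e in evidence
                if e.chrom == seg.chrom and abs(e.position - seg.position) <= window}
        n_near = sum(1 for e in evidence
                     if e.chrom == seg.chrom and abs(e.position - seg.position) <= window)
        if n_near >= min_evidence and len(near) == 1:
            hap = next(iter(near))
            out.append(replace(seg, haplotype_tag=hap))
            events.append(ImputationEvent(seg.read_id, seg.segment_index, seg.chrom,
                                          seg.position, hap, n_near))
        else:
            out.append(seg)
    return out, events


def impute_all(reads: Mapping[str, Sequence[AlignedSegment]],
               window: int = DEFAULT_WINDOW,
               min_evidence: int = 1,
               ) -> tuple[dict[str, list[AlignedSegment]], list[ImputationEvent]]:
    """Apply :func:`impute_phase` independently to every read."""
    updated: dict[str, list[AlignedSegment]] = {}
    events: list[ImputationEvent] = []
    for read_id in sorted(reads):
        segs, ev = impute_phase(reads[read_id], window=window, min_evidence=min_evidence)
        updated[read_id] = segs
        events.extend(ev)
    return updated, events


def phasing_summary(before: Mapping[str, Sequence[AlignedSegment]],
                    after: Mapping[str, Sequence[AlignedSegment]] | None = None,
                    ) -> dict[str, float]:
    """Aggregate phased fractions and within-read concordance.

    Concordance is reported two ways because the natural denominator is
    ambiguous: ``read_concordance_fraction`` is the share of eligible reads
    (>= 2 same-chromosome phased segments) that are fully concordant, and
    ``pair_concordance_fraction`` pools agreeing same-chromosome phased pairs
    over all reads.
    """
    if after is None:
        after = before
    n_segments = sum(len(v) for v in before.values())
    phased_before = sum(1 for v in before.values() for s in v if s.haplotype_tag is not None)
    phased_after = sum(1 for v in after.values() for s in v if s.haplotype_tag is not None)
    eligible = concordant = pairs_total = pairs_agree = 0
    for read_id in sorted(before):
        summary = read_concordance(list(before[read_id]))
        if summary.concordant is not None:
            eligible += 1
            concordant += int(summary.concordant)
        pairs_total += summary.n_pairs_same_chrom
        pairs_agree += summary.n_pairs_agreeing
    return {
        "n_reads": len(before),
        "n_segments": n_segments,
        "phased_fraction_before": phased_before / n_segments if n_segments else 0.0,
        "phased_fraction_after": phased_after / n_segments if n_segments else 0.0,
        "n_reads_concordance_eligible": eligible,
        "read_concordance_fraction": concordant / eligible if eligible else float("nan"),
        "pair_concordance_fraction": pairs_agree / pairs_total if pairs_total else float("nan"),
    }
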