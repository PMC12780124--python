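"""TAD-set comparison: measure of concordance, Jaccard indices, gap fractions.

TopDom-style calls label the genome as ``domain`` (self-interacting region),
``boundary`` (barrier between domains) or ``gap`` (insufficient data to call
anything).  Concordance metrics operate on the domain-labeled intervals only;
gap cataloging quantifies how much of a region class the caller left
uncallable.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

LABELS = ("domain", "boundary", "gap")


@dataclass(frozen=True)
class LabeledInterval:
    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DomainSet:
    """Non-overlapping labeled intervals per chromosome."""

    intervals: list[LabeledInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom = defaultdict(list)
        for iv in self.intervals:
            by_chrom[iv.chrom].append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping intervals on {chrom}: {a} / {b}")

    def with_label(self, label: str) -> list[LabeledInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def domains(self) -> list[LabeledInterval]:
        return self.with_label("domain")


def _overlap(a: LabeledInterval, b: LabeledInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def moc(domains_a: DomainSet, domains_b: DomainSet) -> float:
    """Measure of concordance between two domain partitions, in [0, 1].

    MoC = (sum_ij |A_i n B_j|^2 / (|A_i| |B_j|) - 1) / (sqrt(N_A N_B) - 1),
    summing over all domain pairs; by convention MoC = 1 when both sets hold a
    single domain.  Identical partitions score 1; the metric is symmetric.
    """
    A, B = domains_a.domains, domains_b.domains
    if not A or not B:
        raise ValueError("MoC requires at least one domain in each set")
    na, nb = len(A), len(B)
    if na == 1 and nb == 1:
        return 1.0
    total = 0.0
    for a, b in itertools.product(A, B):
        ov = _overlap(a, b)
        if ov:
            total += ov * ov / (len(a) * len(b))
    return (total - 1.0) / ((na * nb) ** 0.5 - 1.0)


def _merge(intervals: Iterable[LabeledInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for start, end in ivs[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _territory_bp(merged: Mapping[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivs in merged.values() for s, e in ivs)


def _intersection_bp(ma: Mapping[str, list[tuple[int, int]]],
                     mb: Mapping[str, list[tuple[int, int]]]) -> int:
    total = 0
    for chrom in set(ma) & set(mb):
        a, b = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if hi > lo:
                total += hi - lo
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
    return total


def tad_jaccard(domains_a: DomainSet, domains_b: DomainSet,
                mode: str = "any") -> float:
    """Basepair Jaccard index between two domain sets.

    ``mode="any"`` is the Jaccard of the domain-covered territories.
    ``mode="reciprocal25"`` first matches domain pairs requiring each to
    overlap the other by at least 25% of its own length, then reports the
    Jaccard of the matched domains' territories; unmatched domains contribute
    nothing, and no matches at all yields 0.
    """
    A, B = domains_a.domains, domains_b.domains
    if mode == "any":
        ma, mb = _merge(A), _merge(B)
    elif mode == "reciprocal25":
        matched_a, matched_b = [], []
        for a, b in itertools.product(A, B):
            ov = _overlap(a, b)
            if ov >= 0.25 * len(a) and ov >= 0.25 * len(b):
                matched_a.append(a)
                matched_b.append(b)
        if not matched_a:
            return 0.0
        ma, mb = _merge(matched_a), _merge(matched_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    inter = _intersection_bp(ma, mb)
    union = _territory_bp(ma) + _territory_bp(mb) - inter
    return inter / union if union else 0.0


def gap_fraction(domains: DomainSet,
                 regions: Iterable[tuple[str, int, int, str]]) -> dict[str, float]:
    """Percent of each region class's basepairs labeled ``gap``.

    Quantifies how much of e.g. segmental duplications or centromeres the TAD
    caller could not assign; lower is better coverage of the class.
    """
    gaps = _merge(domains.with_label("gap"))
    class_bp: dict[str, int] = defaultdict(int)
    gap_bp: dict[str, int] = defaultdict(int)
    for chrom, start, end, klass in regions:
        if end <= start:
            raise ValueError(f"empty region interval {chrom}:{start}-{end}")
        class_bp[klass] += end - start
        gap_bp[klass] += _intersection_bp({chrom: [(start, end)]}, gaps)
    return {klass: gap_bp[klass] / class_bp[klass] * 100.0 for klass in class_bp}


@dataclass(frozen=True)
class ConcordanceScore:
    """Bundle of domain/matrix concordance statistics (each in [0, 1])."""

    moc: float | None = None
    jaccard_any: float | None = None
    jaccard_reciprocal25: float | None = None
    r_squared: float | None = None


def compare_domains(domains_a: DomainSet, domains_b: DomainSet) -> ConcordanceScore:
    """MoC plus both Jaccard variants for two TAD sets."""
    return ConcordanceScore(
        moc=moc(domains_a, domains_b),
        jaccard_any=tad_jaccard(domains_a, domains_b, mode="any"),
        jaccard_reciprocal25=tad_jaccard(domains_a, domains_b, mode="reciprocal25"),
    )
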