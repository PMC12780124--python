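"""Seeded simulator for diploid genomes and proximity-ligation concatemer reads.

The generator produces ground truth for every downstream stage: a diploid
genome (haplotype 2 differs from haplotype 1 by substitutions at a configured
SNV rate), concatemer reads assembled from restriction fragments of one
haplotype, and per-segment truth records.

Sticky-end ligation model
-------------------------
Cohesive-end religation regenerates the recognition site shared by adjacent
fragments, so a read is assembled as::

    motif[offset:] + core_1 + motif + core_2 + ... + motif + core_n + motif[:offset]

where each ``core`` is a restriction fragment stripped of its boundary motif
bases.  Digesting the read at ``motif_start + cut_offset`` then recovers the
truth segment boundaries exactly, and each segment equals its source fragment
(forward orientation) or the reverse complement of the fragment interval
shifted by ``len(motif) - 2 * cut_offset`` (the bottom-strand interval of the
filled-in sticky ends).  Only palindromic motifs support reverse orientation;
the three preset enzymes all are.

Cis partners are sampled around the read's anchor fragment with probability
proportional to ``d^-alpha`` over fragment-midpoint distance ``d`` (self-pairs
excluded, distances floored at one mean fragment length); each partner is
instead drawn uniformly from another chromosome with probability ``p_trans``.
Each read derives wholly from one haplotype, chosen uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .digest import (DPNII, ConcatemerRead, FragmentMap, RestrictionEnzyme,
                     digest_reference, reverse_complement)
from .contacts import AlignedSegment


@dataclass(frozen=True)
class SegmentCountModel:
    """Distribution of segments per read.

    ``shifted_negbinom``: 1 + NegativeBinomial with dispersion ``dispersion``
    and mean solved numerically so the distribution median equals ``median``
    (the observable the segment-count histograms report).  ``fixed`` emits
    exactly ``value`` segments per read (useful for decay calibration, where
    two-segment reads give directly power-law-distributed pair distances).
    """

    family: str = "shifted_negbinom"
    median: int = 17
    dispersion: float = 3.0
    value: int = 2

    def __post_init__(self) -> None:
        if self.family not in ("shifted_negbinom", "fixed"):
            raise ValueError(f"unknown segment-count family {self.family!r}")
        if self.family == "fixed" and self.value < 1:
            raise ValueError("fixed segment count must be >= 1")
        if self.family == "shifted_negbinom" and self.median < 1:
            raise ValueError("target median must be >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.value, dtype=int)
        mu = _solve_nbinom_mean(self.median, self.dispersion)
        r = self.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p, size=size) + 1


@lru_cache(maxsize=None)
def _solve_nbinom_mean(target_median: int, dispersion: float) -> float:
    """Mean mu of NB(r=dispersion, mu) such that median(1 + NB) == target."""
    target = target_median - 1  # median of the un-shifted NB
    grid = np.logspace(-2, 4, 3000)
    medians = nbinom.median(dispersion, dispersion / (dispersion + grid))
    best = int(np.argmin(np.abs(medians - target)))
    return float(grid[best])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate a DpnII four-cutter concatemer library: a target median
    of 17 segments per read, a single-exponent cis decay (alpha = 1, the
    classic contact-probability scaling), a small trans rate, and a 1.8%
    PCR-duplicate rate; the diploid divergence of 1e-3 substitutions/bp
    matches a typical human heterozygosity.  Chromosome lengths are a
    desk-scale stand-in for real chromosomes.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 600_000})
    snv_rate: float = 1e-3
    enzyme: RestrictionEnzyme = DPNII
    segments_per_read: SegmentCountModel = field(default_factory=SegmentCountModel)
    alpha: float = 1.0
    p_trans: float = 0.05
    n_reads: int = 500
    duplicate_rate: float = 0.018
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_trans", self.p_trans), ("duplicate_rate", self.duplicate_rate),
                        ("snv_rate", self.snv_rate), ("error_rate", self.error_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.duplicate_rate >= 1.0:
            raise ValueError("duplicate_rate must be < 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted segment (reference coordinates, 0-based)."""

    read_id: str
    segment_index: int
    chrom: str
    start: int
    end: int
    strand: str
    haplotype: int
    duplicate_of: str | None = None


@dataclass
class DiploidGenome:
    """Two haplotype sequence sets differing by substitutions only.

    Substitution-only divergence keeps coordinates identical across
    haplotypes, so truth records are valid against either haplotype (and
    against haplotype 1 used as the reference).
    """

    haplotypes: dict[int, dict[str, str]]
    variants: pd.DataFrame  # columns: chrom, pos, ref, alt

    @property
    def reference(self) -> dict[str, str]:
        return self.haplotypes[1]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> DiploidGenome:
    """Generate a diploid genome: haplotype 1 random, haplotype 2 mutated.

    Substitutions are drawn per base at ``config.snv_rate``; each variant
    replaces the reference base with a uniformly chosen different base.
    Fully reproducible from the config seed.
    """
    rng = config.rng() if rng is None else rng
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    rows = []
    for chrom, length in config.chrom_lengths.items():
        codes = _random_sequence(rng, length)
        alt_codes = codes.copy()
        if config.snv_rate > 0:
            hits = np.flatnonzero(rng.random(length) < config.snv_rate)
            offsets = rng.integers(1, 4, size=hits.size, dtype=np.uint8)
            alt_codes[hits] = (codes[hits] + offsets) % 4
            for pos in hits:
                rows.append((chrom, int(pos), _to_str(codes[pos:pos + 1]),
                             _to_str(alt_codes[pos:pos + 1])))
        hap1[chrom] = _to_str(codes)
        hap2[chrom] = _to_str(alt_codes)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return DiploidGenome(haplotypes={1: hap1, 2: hap2}, variants=variants)


@dataclass
class _FragmentUniverse:
    """Interior restriction fragments of one haplotype, indexed for sampling."""

    chroms: list[str]
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    mids: dict[str, np.ndarray]
    flat: list[tuple[str, int]]  # (chrom, local index), anchor sampling universe
    others: dict[str, list[tuple[str, int]]]  # trans candidates per anchor chrom
    mean_len: float


def _build_universe(hap_seqs: Mapping[str, str],
                    enzyme: RestrictionEnzyme) -> _FragmentUniverse:
    fmap = digest_reference(hap_seqs, enzyme)
    m = len(enzyme.motif)
    chroms, starts, ends, mids, flat = [], {}, {}, {}, []
    lengths = []
    for chrom in fmap.chrom_lengths:
        frags = fmap.by_chrom(chrom)
        # interior fragments only: both boundaries are genuine cut sites, so
        # sticky ends exist on both sides; also require room for the motif
        interior = [f for f in frags[1:-1] if len(f) >= m]
        if not interior:
            continue
        chroms.append(chrom)
        starts[chrom] = np.array([f.start for f in interior])
        ends[chrom] = np.array([f.end for f in interior])
        mids[chrom] = (starts[chrom] + ends[chrom]) / 2.0
        flat.extend((chrom, i) for i in range(len(interior)))
        lengths.extend(len(f) for f in interior)
    if not flat:
        raise ValueError("no usable interior restriction fragments; "
                         "chromosomes too short for the chosen enzyme")
    others = {chrom: [(c, i) for (c, i) in flat if c != chrom] for chrom in chroms}
    return _FragmentUniverse(chroms, starts, ends, mids, flat, others,
                             mean_len=float(np.mean(lengths)))


def simulate_concatemers(config: SimulationConfig,
                         genome: DiploidGenome,
                         rng: np.random.Generator | None = None,
                         verify: bool = True,
                         ) -> tuple[list[ConcatemerRead], list[TruthRecord]]:
    """Emit concatemer reads with per-segment truth records.

    ``verify`` re-digests every error-free read and asserts that the recovered
    boundaries match the truth — a cheap internal consistency check of the
    ligation-junction model (skipped automatically when ``error_rate > 0``).
    A read whose chromosome offers fewer cis partners than requested is
    truncated (the shortfall is reflected in its truth records).
    """
    from .digest import digest_read, find_cut_sites  # local: avoids cycle at import

    rng = config.rng() if rng is None else rng
    enzyme = config.enzyme
    m, o = len(enzyme.motif), enzyme.cut_offset
    shift = m - 2 * o
    allow_reverse = enzyme.is_palindromic

    universes = {hap: _build_universe(genome.haplotypes[hap], enzyme)
                 for hap in (1, 2)}
    counts = config.segments_per_read.sample(rng, config.n_reads)
    haps = rng.integers(1, 3, size=config.n_reads)
    reads: list[ConcatemerRead] = []
    truth: list[TruthRecord] = []
    width = len(str(config.n_reads))

    for r in range(config.n_reads):
        hap = int(haps[r])
        uni = universes[hap]
        hap_seqs = genome.haplotypes[hap]
        read_id = f"read{r:0{width}d}"
        n_target = int(counts[r])

        a_chrom, a_idx = uni.flat[rng.integers(len(uni.flat))]
        chosen: list[tuple[str, int]] = [(a_chrom, a_idx)]
        # cis weights around the anchor, computed once per read
        d = np.abs(uni.mids[a_chrom] - uni.mids[a_chrom][a_idx])
        with np.errstate(divide="ignore"):
            cis_w = np.maximum(d, uni.mean_len) ** -config.alpha
        cis_w[a_idx] = 0.0
        cis_cum = np.cumsum(cis_w)
        cis_total = float(cis_cum[-1]) if cis_cum.size else 0.0
        other = uni.others[a_chrom]

        for _ in range(n_target - 1):
            go_trans = other and rng.random() < config.p_trans
            if go_trans:
                chosen.append(other[rng.integers(len(other))])
            elif cis_total > 0:
                pick = int(np.searchsorted(cis_cum, rng.random() * cis_total,
                                           side="right"))
                pick = min(pick, len(cis_w) - 1)
                chosen.append((a_chrom, pick))
            elif other:
                chosen.append(other[rng.integers(len(other))])
            else:
                break  # fragment universe exhausted: truncate

        parts = [enzyme.motif[o:]]
        for k, (chrom, idx) in enumerate(chosen):
            s = int(uni.starts[chrom][idx])
            e = int(uni.ends[chrom][idx])
            core = hap_seqs[chrom][s + (m - o): e - o]
            strand = "+"
            if allow_reverse and rng.random() < 0.5:
                strand = "-"
                core = reverse_complement(core)
            if k > 0:
                parts.append(enzyme.motif)
            parts.append(core)
            if strand == "+":
                truth.append(TruthRecord(read_id, k, chrom, s, e, "+", hap))
            else:
                truth.append(TruthRecord(read_id, k, chrom, s + shift, e + shift, "-", hap))
        parts.append(enzyme.motif[:o])
        sequence = "".join(parts)

        if config.error_rate > 0:
            codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
            base_idx = np.searchsorted(_BASES, codes)  # ACGT are sorted bytes
            hits = np.flatnonzero(rng.random(len(sequence)) < config.error_rate)
            base_idx[hits] = (base_idx[hits] + rng.integers(1, 4, size=hits.size)) % 4
            sequence = _to_str(base_idx.astype(np.uint8))
        elif verify:
            expected = []
            pos = 0
            for (chrom, idx) in chosen:
                seg_len = int(uni.ends[chrom][idx] - uni.starts[chrom][idx])
                expected.append(pos + seg_len)
                pos += seg_len
            got = [0, *find_cut_sites(sequence, enzyme), len(sequence)]
            if got[1:] != expected:
                raise AssertionError(
                    f"{read_id}: junction model produced spurious or missing cut sites")

        reads.append(ConcatemerRead(read_id, sequence, qualities="I" * len(sequence)))

    return reads, truth


def inject_duplicates(reads: Sequence[ConcatemerRead],
                      truth: Sequence[TruthRecord],
                      rate: float,
                      rng: np.random.Generator) -> tuple[list[ConcatemerRead], list[TruthRecord]]:
    """Append a PCR copy of each read with probability ``rate``.

    Duplicates get fresh read ids with ``duplicate_of`` provenance in their
    truth records; with ``rate == 0`` the input is returned unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"duplicate rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return list(reads), list(truth)
    truth_by_read: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        truth_by_read.setdefault(rec.read_id, []).append(rec)
    out_reads = list(reads)
    out_truth = list(truth)
    flips = rng.random(len(reads)) < rate
    for read, dup in zip(reads, flips):
        if not dup:
            continue
        dup_id = f"{read.read_id}:dup"
        out_reads.append(ConcatemerRead(dup_id, read.sequence, read.qualities))
        for rec in truth_by_read.get(read.read_id, []):
            out_truth.append(replace(rec, read_id=dup_id, duplicate_of=read.read_id))
    return out_reads, out_truth


def truth_to_alignments(truth: Sequence[TruthRecord],
                        mapq: int = 60,
                        mapq_choices: Sequence[int] | None = None,
                        tag_fraction: float = 0.0,
                        rng: np.random.Generator | None = None,
                        ) -> dict[str, list[AlignedSegment]]:
    """Turn truth records into perfect alignments, grouped by read.

    Stands in for a real aligner so the downstream stages are testable
    deterministically: MAPQ is ``mapq`` everywhere, or drawn uniformly from
    ``mapq_choices`` to exercise filters.  ``tag_fraction`` tags that fraction
    of segments with their true haplotype (the rest stay unphased), emulating
    sparse haplotagging ahead of imputation.
    """
    if (mapq_choices is not None or tag_fraction > 0) and rng is None:
        raise ValueError("rng is required for randomized MAPQ or tagging")
    grouped: dict[str, list[AlignedSegment]] = {}
    for rec in truth:
        q = int(rng.choice(mapq_choices)) if mapq_choices is not None else mapq
        tag = rec.haplotype if (tag_fraction > 0 and rng.random() < tag_fraction) else None
        grouped.setdefault(rec.read_id, []).append(AlignedSegment(
            read_id=rec.read_id, segment_index=rec.segment_index,
            chrom=rec.chrom, ref_start=rec.start, ref_end=rec.end,
            strand=rec.strand, mapq=q, haplotype_tag=tag))
    for segs in grouped.values():
        segs.sort(key=lambda s: s.segment_index)
    return grouped


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: DiploidGenome
    reads: list[ConcatemerRead]
    truth: list[TruthRecord]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: genome, concatemers, then PCR duplicates."""
    rng = config.rng()
    genome = simulate_genome(config, rng)
    reads, truth = simulate_concatemers(config, genome, rng)
    reads, truth = inject_duplicates(reads, truth, config.duplicate_rate, rng)
    return SimulationResult(config=config, genome=genome, reads=reads, truth=truth)
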