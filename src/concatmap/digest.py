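"""In silico restriction digestion.

Proximity-ligation concatemer reads are split back into their constituent
segments at the recognition sites of the enzyme used to prepare the library;
the same scanner digests a reference genome into the restriction-fragment map
used for fragment assignment.

All coordinates in this module are 0-based half-open.  Conversion to 1-based
conventions happens only in the serialization layer (:mod:`concatmap.io`).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

# IUPAC nucleotide codes -> the set of concrete bases each matches.  An 'N' in
# the *subject* sequence never matches any motif code (masked regions must not
# produce cut sites), so 'N' is deliberately absent from every expansion below.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MotifError(ValueError):
    """Raised for an invalid recognition motif or cut offset."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a recognition motif plus a top-strand cut offset.

    ``cut_offset`` is the distance from the motif start to the cut position on
    the top strand, so ``0 <= cut_offset <= len(motif)``:  DpnII cuts ^GATC
    (offset 0), HindIII cuts A^AGCTT (offset 1), NlaIII cuts CATG^ (offset 4).
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        if not motif:
            raise MotifError("recognition motif must be non-empty")
        bad = set(motif) - set(IUPAC_CODES)
        if bad:
            raise MotifError(f"invalid IUPAC code(s) in motif {self.motif!r}: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(motif):
            raise MotifError(
                f"cut offset {self.cut_offset} outside motif of length {len(motif)}")
        object.__setattr__(self, "motif", motif)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.motif) == self.motif

    def _pattern(self, motif: str) -> re.Pattern[str]:
        # lookahead so that overlapping occurrences are all found
        body = "".join(f"[{IUPAC_CODES[c]}]" for c in motif)
        return re.compile(f"(?={body})")

    def motif_starts(self, sequence: str) -> list[int]:
        """Start positions of every top-strand motif occurrence (overlaps included)."""
        seq = sequence.upper()
        return [m.start() for m in self._pattern(self.motif).finditer(seq)]


DPNII = RestrictionEnzyme("DpnII", "GATC", 0)
HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1)
NLAIII = RestrictionEnzyme("NlaIII", "CATG", 4)

PRESET_ENZYMES: Mapping[str, RestrictionEnzyme] = {
    "dpnii": DPNII,
    "hindiii": HINDIII,
    "nlaiii": NLAIII,
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Resolve a preset name or a ``MOTIF@OFFSET`` custom enzyme string."""
    key = name.strip().lower()
    if key in PRESET_ENZYMES:
        return PRESET_ENZYMES[key]
    if "@" in name:
        motif, _, offset = name.partition("@")
        try:
            return RestrictionEnzyme(f"custom({motif.upper()}@{offset})", motif, int(offset))
        except ValueError as exc:
            raise MotifError(f"cannot parse custom enzyme {name!r}: {exc}") from exc
    raise MotifError(
        f"unknown enzyme {name!r}; use one of {sorted(PRESET_ENZYMES)} or MOTIF@OFFSET")


@dataclass(frozen=True)
class ConcatemerRead:
    """One long concatemer read carrying multiple ligated restriction fragments."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadSegment:
    """One deconcatenated piece of a read, delimited by restriction cut sites."""

    read_id: str
    segment_index: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut positions of ``enzyme`` in ``sequence`` (sorted, deduplicated).

    Cut positions are ``motif_start + cut_offset`` for every top-strand motif
    occurrence.  For a non-palindromic motif the bottom strand is scanned as
    well by matching the reverse-complement motif on the top strand; a
    bottom-strand cut ``cut_offset`` bases from that strand's 5' end maps to
    top-strand coordinate ``match_start + len(motif) - cut_offset``.

    Positions 0 and ``len(sequence)`` are dropped: they delimit empty segments.
    """
    seq = sequence.upper()
    cuts = {s + enzyme.cut_offset for s in enzyme.motif_starts(seq)}
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.motif)
        pat = enzyme._pattern(rc)
        m = len(enzyme.motif)
        cuts.update(mt.start() + m - enzyme.cut_offset for mt in pat.finditer(seq))
    cuts.discard(0)
    cuts.discard(len(seq))
    return sorted(cuts)


def digest_read(read: ConcatemerRead, enzyme: RestrictionEnzyme,
                min_length: int = 0) -> list[ReadSegment]:
    """Split a concatemer read at the enzyme's cut sites.

    ``k`` interior cut positions yield ``k + 1`` segments that exactly tile the
    read.  A read containing no recognition site is returned as one segment.
    ``min_length`` optionally drops segments shorter than that many bases
    (default 0: keep everything); segment indices are assigned after dropping.
    """
    cuts = find_cut_sites(read.sequence, enzyme)
    bounds = [0, *cuts, len(read.sequence)]
    segments = []
    idx = 0
    for start, end in zip(bounds, bounds[1:]):
        if end - start < max(min_length, 1):
            continue
        segments.append(ReadSegment(read.read_id, idx, start, end,
                                    read.sequence[start:end]))
        idx += 1
    return segments


@dataclass(frozen=True)
class Fragment:
    """A reference restriction fragment (interval between consecutive cut sites)."""

    fragment_id: int
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class FragmentMap:
    """Per-chromosome restriction fragments exactly tiling each chromosome.

    Fragment ids are global 0-based indices in (chromosome, start) order, so a
    fragment can be recovered from its id in O(1).
    """

    chrom_lengths: dict[str, int]
    fragments: list[Fragment] = field(default_factory=list)
    _starts: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _chrom_first: dict[str, int] = field(default_factory=dict, repr=False)

    def by_chrom(self, chrom: str) -> list[Fragment]:
        first = self._chrom_first[chrom]
        return self.fragments[first:first + len(self._starts[chrom])]

    def __len__(self) -> int:
        return len(self.fragments)


def digest_reference(genome: Mapping[str, str] | Iterable[tuple[str, str]],
                     enzyme: RestrictionEnzyme) -> FragmentMap:
    """Digest reference sequences into a :class:`FragmentMap`.

    Terminal fragments (before the first and after the last cut site) are
    included, so the fragments of each chromosome tile ``[0, length)``.
    """
    items = genome.items() if isinstance(genome, Mapping) else list(genome)
    fmap = FragmentMap(chrom_lengths={})
    fid = 0
    for chrom, seq in items:
        if chrom in fmap.chrom_lengths:
            raise ValueError(f"duplicate chromosome name {chrom!r}")
        if not seq:
            raise ValueError(f"chromosome {chrom!r} is empty")
        cuts = find_cut_sites(seq, enzyme)
        bounds = [0, *cuts, len(seq)]
        starts = []
        fmap._chrom_first[chrom] = fid
        for start, end in zip(bounds, bounds[1:]):
            fmap.fragments.append(Fragment(fid, chrom, start, end))
            starts.append(start)
            fid += 1
        fmap.chrom_lengths[chrom] = len(seq)
        fmap._starts[chrom] = starts
    return fmap


def assign_to_fragment(chrom: str, position: int, fmap: FragmentMap) -> Fragment:
    """The unique fragment whose half-open interval contains ``position``."""
    if chrom not in fmap.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not 0 <= position < fmap.chrom_lengths[chrom]:
        raise ValueError(
            f"position {position} outside {chrom} [0, {fmap.chrom_lengths[chrom]})")
    starts = fmap._starts[chrom]
    local = bisect_right(starts, position) - 1
    return fmap.fragments[fmap._chrom_first[chrom] + local]
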