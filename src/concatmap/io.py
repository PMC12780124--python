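"""Readers and writers for the standard formats the pipeline touches.

Internally everything is 0-based half-open; 1-based conventions (pairs text
format, SAM POS) are applied only here, on the way in or out.  FASTA/FASTQ go
through Biopython, SAM through pysam; pairs, BED, TSV and the COO matrix
container are simple line formats written with explicit header comments
declaring their coordinate convention.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import AlignedSegment, ContactPair, MockPairedRecord
from .digest import ConcatemerRead, FragmentMap
from .domains import DomainSet, LabeledInterval
from .matrix import ContactMatrix

PAIRS_COLUMNS = "readID chrom1 pos1 chrom2 pos2 strand1 strand2 mapq1 mapq2"
SEGMENT_COLUMNS = ("read_id", "segment_index", "chrom", "start", "end",
                   "strand", "mapq", "haplotype")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_reads(path: str | Path) -> list[ConcatemerRead]:
    """Concatemer reads from FASTA or FASTQ (gzip-transparent, by extension)."""
    suffixes = Path(path).suffixes
    stem = [s for s in suffixes if s != ".gz"]
    fmt = "fastq" if stem and stem[-1] in (".fastq", ".fq") else "fasta"
    out = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            quals = None
            if "phred_quality" in rec.letter_annotations:
                quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(ConcatemerRead(rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(reads: Iterable[ConcatemerRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            quals = read.qualities or "I" * len(read.sequence)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")


# ------------------------------------------------------------- segment tables

def write_segments_tsv(reads: Mapping[str, Sequence[AlignedSegment]],
                       path: str | Path) -> None:
    """Aligned-segment table, one row per segment (0-based half-open)."""
    with _open_text(path, "wt") as handle:
        handle.write("# aligned segments; coordinates 0-based half-open\n")
        handle.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for read_id in sorted(reads):
            for s in reads[read_id]:
                chrom = s.chrom if s.is_mapped else "."
                hap = str(s.haplotype_tag) if s.haplotype_tag is not None else "."
                handle.write(f"{s.read_id}\t{s.segment_index}\t{chrom}\t"
                             f"{s.ref_start}\t{s.ref_end}\t{s.strand}\t{s.mapq}\t{hap}\n")


def read_segments_tsv(path: str | Path) -> dict[str, list[AlignedSegment]]:
    reads: dict[str, list[AlignedSegment]] = {}
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("read_id"):
                continue
            rid, idx, chrom, start, end, strand, mapq, hap = line.rstrip("\n").split("\t")
            mapped = chrom != "."
            reads.setdefault(rid, []).append(AlignedSegment(
                read_id=rid, segment_index=int(idx),
                chrom=chrom if mapped else None,
                ref_start=int(start), ref_end=int(end) if mapped else int(start) + 1,
                strand=strand if mapped else "+",
                mapq=int(mapq),
                haplotype_tag=int(hap) if hap != "." else None))
    for segs in reads.values():
        segs.sort(key=lambda s: s.segment_index)
    return reads


def read_segments_sam(path: str | Path,
                      delimiter: str = ":") -> dict[str, list[AlignedSegment]]:
    """Ingest per-segment alignments from SAM/BAM.

    Each record is one segment; the parent read and segment index are
    recovered from the query name as ``readid<delimiter>segindex``.  A record
    whose name lacks the delimiter convention is treated as segment 0 of its
    own read.  Haplotype tags are read from HP.
    """
    reads: dict[str, list[AlignedSegment]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name or ""
            rid, _, idx = name.rpartition(delimiter)
            if not rid or not idx.isdigit():
                rid, idx = name, "0"
            hp = rec.get_tag("HP") if rec.has_tag("HP") else None
            if rec.is_unmapped:
                seg = AlignedSegment(rid, int(idx), None, 0, 1, "+", 0, hp)
            else:
                seg = AlignedSegment(
                    read_id=rid, segment_index=int(idx),
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start, ref_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality, haplotype_tag=hp)
            reads.setdefault(rid, []).append(seg)
    for segs in reads.values():
        segs.sort(key=lambda s: s.segment_index)
    return reads


# ----------------------------------------------------------------- pairs text

def write_pairs(pairs: Iterable[ContactPair],
                chrom_lengths: Mapping[str, int],
                path: str | Path,
                metadata: Mapping[str, object] | None = None) -> None:
    """Contact pairs in the 4DN pairs text format (positions 1-based on disk)."""
    with _open_text(path, "wt") as handle:
        handle.write("## pairs format v1.0\n")
        handle.write("#shape: upper triangle\n")
        for chrom, length in chrom_lengths.items():
            handle.write(f"#chromsize: {chrom} {length}\n")
        for key, value in (metadata or {}).items():
            handle.write(f"#{key}: {value}\n")
        handle.write(f"#columns: {PAIRS_COLUMNS}\n")
        for p in pairs:
            c1 = p.chrom1 or "!"
            c2 = p.chrom2 or "!"
            handle.write(f"{p.read_id}:{p.index1}-{p.index2}\t{c1}\t{p.pos1 + 1}\t"
                         f"{c2}\t{p.pos2 + 1}\t{p.strand1}\t{p.strand2}\t"
                         f"{p.mapq1}\t{p.mapq2}\n")


def read_pairs(path: str | Path) -> tuple[list[ContactPair], dict[str, int]]:
    pairs: list[ContactPair] = []
    chrom_lengths: dict[str, int] = {}
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    _, chrom, length = line.split()
                    chrom_lengths[chrom] = int(length)
                continue
            rid_idx, c1, p1, c2, p2, s1, s2, q1, q2 = line.rstrip("\n").split("\t")
            rid, _, span = rid_idx.rpartition(":")
            i1, _, i2 = span.partition("-")
            pairs.append(ContactPair(
                read_id=rid, index1=int(i1), index2=int(i2),
                chrom1=None if c1 == "!" else c1, pos1=int(p1) - 1, strand1=s1,
                mapq1=int(q1),
                chrom2=None if c2 == "!" else c2, pos2=int(p2) - 1, strand2=s2,
                mapq2=int(q2)))
    return pairs, chrom_lengths


# ------------------------------------------------------------------ mock SAM

def write_mock_sam(records: Iterable[MockPairedRecord],
                   chrom_lengths: Mapping[str, int],
                   path: str | Path) -> None:
    """Mock paired-end records as SAM with mandatory pairing flags set."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "wh", header=pysam.AlignmentHeader.from_dict(header)) as out:
        refs = {c: i for i, c in enumerate(chrom_lengths)}
        for rec in records:
            for mate, other in ((rec.mate1, rec.mate2), (rec.mate2, rec.mate1)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.template_id
                flag = 0x1  # paired
                flag |= 0x40 if mate.is_first else 0x80
                if mate.chrom is None:
                    flag |= 0x4
                elif mate.strand == "-":
                    flag |= 0x10
                if other.chrom is None:
                    flag |= 0x8
                elif other.strand == "-":
                    flag |= 0x20
                a.flag = flag
                if mate.chrom is not None:
                    a.reference_id = refs[mate.chrom]
                    a.reference_start = mate.pos
                    a.mapping_quality = mate.mapq
                if other.chrom is not None:
                    a.next_reference_id = refs[other.chrom]
                    a.next_reference_start = other.pos
                if mate.sequence:
                    a.query_sequence = mate.sequence
                    a.cigarstring = f"{len(mate.sequence)}M" if mate.chrom else None
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(mate.sequence))
                out.write(a)


# ------------------------------------------------------------------ BED forms

def write_fragments_bed(fmap: FragmentMap, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("# restriction fragments; BED 0-based half-open\n")
        for frag in fmap.fragments:
            handle.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\tfragment_{frag.fragment_id}\n")


def read_bed_classes(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED intervals with a 4th class/label column (0-based half-open)."""
    out = []
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("track") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else "region"
            out.append((chrom, start, end, label))
    return out


def read_domains_bed(path: str | Path) -> DomainSet:
    """TAD calls: BED with a domain/boundary/gap label in column 4."""
    return DomainSet([LabeledInterval(*iv) for iv in read_bed_classes(path)])


def write_domains_bed(domains: DomainSet, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("# TAD classification; BED 0-based half-open; label in column 4\n")
        for iv in sorted(domains.intervals, key=lambda v: (v.chrom, v.start)):
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ------------------------------------------------------------------ matrices

def write_matrix_coo(matrix: ContactMatrix, path: str | Path) -> None:
    """Plain-text COO triples with a JSON header describing the binning."""
    header = {"chrom_lengths": matrix.chrom_lengths, "bin_size": matrix.bin_size}
    with _open_text(path, "wt") as handle:
        handle.write(f"#{json.dumps(header)}\n")
        handle.write("#bin1\tbin2\tcount  (genome-wide bin indices, upper triangle)\n")
        for (i, j) in sorted(matrix.counts):
            count = matrix.counts[(i, j)]
            text = f"{count:g}"
            handle.write(f"{i}\t{j}\t{text}\n")


def read_matrix_coo(path: str | Path) -> ContactMatrix:
    with _open_text(path) as handle:
        first = handle.readline()
        if not first.startswith("#"):
            raise ValueError("COO matrix file lacks its JSON header line")
        meta = json.loads(first[1:])
        matrix = ContactMatrix(meta["chrom_lengths"], meta["bin_size"])
        for line in handle:
            if line.startswith("#"):
                continue
            i, j, count = line.split()
            matrix.counts[(int(i), int(j))] = float(count)
    return matrix


# ------------------------------------------------------------------- summary

def write_summary(summary: Mapping[str, object], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=float)
        handle.write("\n")
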