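"""End-to-end pipeline: digest -> align-ingest -> expand -> filter -> dedup ->
phase -> matrices, with machine-readable per-stage summaries.

Two entry modes share the same stage chain: simulation mode generates the
genome, reads and truth alignments itself (download-free testing), while
ingest mode consumes an existing segment-alignment table (TSV dialect or
SAM/BAM with ``readid:segindex`` query names).  Re-running with an identical
config produces byte-identical text outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .contacts import expand_reads, filter_pairs, mark_duplicates, segment_stats
from .digest import RestrictionEnzyme, get_enzyme
from .matrix import bin_contacts, kr_balance
from .phasing import DEFAULT_WINDOW, impute_all, phasing_summary
from .simulate import SimulationConfig, simulate, truth_to_alignments

logger = logging.getLogger("concatmap")

DEFAULT_BIN_SIZES = (2_500_000, 50_000)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the method's published conventions.

    MAPQ >= 1 for contact filtering, a 30-Mbp phase-imputation window and
    2.5-Mbp / 50-kbp matrix resolutions as presets.
    """

    out_dir: str | Path
    enzyme: str | RestrictionEnzyme = "DpnII"
    mapq_min: int = 1
    phasing_window: int = DEFAULT_WINDOW
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES
    mate_length: int = 150
    seed: int = 0
    simulation: SimulationConfig | None = None
    # fraction of simulated segments carrying their true haplotype tag,
    # emulating sparse upstream haplotagging ahead of imputation
    tag_fraction: float = 0.25
    segments_path: str | Path | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def resolved_enzyme(self) -> RestrictionEnzyme:
        if isinstance(self.enzyme, RestrictionEnzyme):
            return self.enzyme
        return get_enzyme(self.enzyme)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full stage chain and write artifacts under ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``);
    every stage contributes its in/out counts so conservation invariants are
    checkable from the summary alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {
        "enzyme": config.resolved_enzyme().name,
        "mapq_min": config.mapq_min,
        "phasing_window": config.phasing_window,
        "bin_sizes": list(config.bin_sizes),
        "seed": config.seed,
    }}

    # --- stage: acquire segments (simulate, or ingest an alignment table)
    try:
        if config.simulation is not None:
            sim = simulate(config.simulation)
            chrom_lengths = dict(config.simulation.chrom_lengths)
            tag_rng = np.random.default_rng((config.seed * 7919 + 11) % (2**31 - 1))
            reads = truth_to_alignments(sim.truth,
                                        tag_fraction=config.tag_fraction,
                                        rng=tag_rng)
            cio.write_fasta(sim.genome.reference, out / "genome_hap1.fa")
            cio.write_fasta(sim.genome.haplotypes[2], out / "genome_hap2.fa")
            cio.write_fastq(sim.reads, out / "reads.fastq")
            summary["simulate"] = {"n_reads": len(sim.reads),
                                   "n_truth_segments": len(sim.truth)}
        elif config.segments_path is not None:
            path = str(config.segments_path)
            if path.endswith((".sam", ".bam")):
                reads = cio.read_segments_sam(path)
            else:
                reads = cio.read_segments_tsv(path)
            chrom_lengths = dict(config.chrom_lengths)
            if not chrom_lengths:
                for segs in reads.values():
                    for s in segs:
                        if s.is_mapped:
                            chrom_lengths[s.chrom] = max(
                                chrom_lengths.get(s.chrom, 0), s.ref_end)
        else:
            raise ValueError("config needs either a simulation or a segments_path")
    except Exception as exc:
        raise StageError(f"stage 'ingest' failed: {exc}") from exc

    n_segments = sum(len(v) for v in reads.values())
    summary["ingest"] = {"n_reads": len(reads), "n_segments": n_segments}
    logger.info("ingest: %d reads, %d segments", len(reads), n_segments)
    cio.write_segments_tsv(reads, out / "segments.tsv")

    if not reads:
        summary.update({"stats": {}, "dedup": {"n_reads": 0, "n_duplicates": 0, "rate": 0.0},
                        "expand": {"n_pairs": 0}, "filter": {"total": 0, "retained": 0,
                                                             "unmapped_mate": 0, "low_mapq": 0},
                        "phasing": {}, "matrices": {}})
        cio.write_pairs([], chrom_lengths, out / "contacts.pairs",
                        metadata={"mapq_min": config.mapq_min})
        cio.write_summary(summary, out / "summary.json")
        return summary

    # --- stage: segment statistics
    summary["stats"] = segment_stats(reads)

    # --- stage: duplicate marking (read level, before pair expansion)
    dup = mark_duplicates(reads)
    unique_reads = {rid: segs for rid, segs in reads.items()
                    if rid not in dup.duplicates}
    summary["dedup"] = {"n_reads": dup.n_reads, "n_duplicates": len(dup.duplicates),
                        "rate": dup.rate}
    logger.info("dedup: flagged %d/%d reads (%.2f%%)", len(dup.duplicates),
                dup.n_reads, dup.rate * 100)

    # --- stage: pairwise expansion and MAPQ filtering
    pairs = expand_reads(unique_reads)
    retained, tally = filter_pairs(pairs, mapq_min=config.mapq_min)
    summary["expand"] = {"n_pairs": len(pairs)}
    summary["filter"] = tally.as_dict()
    logger.info("expand: %d pairs; filter: retained %d (unmapped %d, low MAPQ %d)",
                len(pairs), tally.retained, tally.unmapped_mate, tally.low_mapq)
    cio.write_pairs(retained, chrom_lengths, out / "contacts.pairs",
                    metadata={"mapq_min": config.mapq_min})

    # --- stage: phase imputation
    phased, events = impute_all(unique_reads, window=config.phasing_window)
    summary["phasing"] = phasing_summary(unique_reads, phased)
    summary["phasing"]["n_imputed"] = len(events)
    cio.write_segments_tsv(phased, out / "phased.tsv")

    # --- stage: matrices at each preset resolution, KR per chromosome
    summary["matrices"] = {}
    for bin_size in config.bin_sizes:
        try:
            matrix = bin_contacts(retained, chrom_lengths, bin_size)
        except Exception as exc:
            raise StageError(f"stage 'matrix@{bin_size}' failed: {exc}") from exc
        cio.write_matrix_coo(matrix, out / f"matrix_{bin_size}.coo")
        balance_status = {}
        for chrom in chrom_lengths:
            sub = matrix.cis_submatrix(chrom)
            if sub.sum() == 0:
                balance_status[chrom] = "empty"
                continue
            balance_status[chrom] = kr_balance(sub).status
        summary["matrices"][str(bin_size)] = {
            "total_contacts": matrix.total,
            "n_bins": matrix.n_bins,
            "kr_status": balance_status,
        }

    cio.write_summary(summary, out / "summary.json")
    return summary
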