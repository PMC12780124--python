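# concatmap

Processing of multi-contact concatemer reads from chromosome conformation
capture (3C) with long-read sequencing.

## The problem

Classical Hi-C reads proximity-ligation products as short paired-end
fragments: each read pair reports exactly one chromatin contact, and short
reads map poorly across repeats, segmental duplications and centromeres.
Coupling 3C with long-read sequencing instead yields *concatemer* reads —
single multi-kilobase reads containing many ligated restriction fragments
(segments), each a participant in the same spatial neighborhood.  A read with
*n* aligned segments represents all

    C(n, 2) = n(n - 1) / 2

pairwise interactions: 17 segments expand to 136 contacts, the information
content of 272 short paired-end reads.  Longer segments also map and phase
better, so long-read 3C recovers contacts and haplotype structure in genomic
territory that defeats short-read Hi-C.

`concatmap` implements the computational core of this workflow for people
analyzing such libraries:

- **in silico digestion** — split concatemer reads at the recognition sites
  of the library enzyme (DpnII `^GATC`, HindIII `A^AGCTT`, NlaIII `CATG^`, or
  any custom IUPAC motif with a cut offset), and digest reference genomes
  into restriction-fragment maps;
- **pairwise expansion** — convert each read's aligned segments into all
  C(n, 2) contact pairs, written in the 4DN pairs text format, plus mock
  Illumina-like paired-end SAM records for scaffolders;
- **filtering and deduplication** — both-mates-mapped + MAPQ thresholding
  with exact rejection tallies, and alignment-fingerprint PCR-duplicate
  marking;
- **haplotype phase imputation** — segments of one read derive from one
  chromosomal fiber, so an unphased segment inherits the haplotype when all
  phased segments of the read on its chromosome within 30 Mbp agree (the
  conservative single-pass rule; original tags are never overwritten);
- **contact matrices** — symmetric binning at any resolution (2.5-Mbp and
  50-kbp presets), Knight–Ruiz balancing (diagonal scaling `W M W` with equal
  row sums; non-convergence and disconnected matrices are explicit failure
  statuses, as happens on real pericentromeric chromosomes), and squared
  Pearson correlation between matrices;
- **TAD concordance** — the measure of concordance between two domain
  partitions

      MoC = ( Σ_ij |A_i ∩ B_j|² / (|A_i||B_j|) − 1 ) / ( √(N_A N_B) − 1 ),

  basepair Jaccard with any-overlap or 25%-reciprocal-overlap matching, and
  gap-fraction cataloging per annotation class;
- **a seeded simulator** — diploid genome with SNVs, sticky-end-ligation
  concatemers with power-law cis decay `P(d) ∝ d^−α` and a configurable
  trans rate, and PCR duplicates, with per-segment ground truth, so every
  stage above is testable without external data.

## Worked example

Run the simulated pipeline end to end (digest → expand → filter → dedup →
phase → matrices):

```python
from concatmap import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo", seed=7, bin_sizes=(50_000,),
    simulation=SimulationConfig(seed=7, n_reads=500,
                                chrom_lengths={"chr1": 1_000_000,
                                               "chr2": 600_000}))
summary = run_pipeline(config)
```

The summary this prints (also written to `demo/summary.json`):

```
ingest    n_reads 507      n_segments 9238       # 500 reads + 7 PCR duplicates
dedup     n_duplicates 7   rate 0.0138           # fingerprint-identical reads flagged
expand    n_pairs 108048                         # sum of C(n,2) over unique reads
filter    retained 108048  unmapped 0  low_mapq 0
phasing   phased_fraction_before 0.258           # sparse upstream haplotagging
          phased_fraction_after  0.951           # after 30-Mbp imputation
          read_concordance_fraction 1.0          # single-fiber reads agree fully
matrices  50000: total_contacts 108048, kr_status chr1/chr2 converged
```

Segments-per-read statistics for the same run (`summary["stats"]`): mean
18.2, median 16, sd 10.9 — the simulator's shifted negative binomial around
its target median.  Every pair is conserved from expansion through binning:
`total_contacts` equals the retained pair count exactly.

Artifacts written: `segments.tsv`, `contacts.pairs` (4DN pairs format,
1-based on disk), `phased.tsv`, `matrix_50000.coo`, `reads.fastq`,
`genome_hap1.fa`/`genome_hap2.fa`, `summary.json`.

The same stages are available as subcommands of the `concatmap` CLI:
`digest`, `digest-ref`, `pairs`, `mock-pe`, `dedup`, `phase`, `stats`,
`matrix`, `compare-matrix`, `class-profile`, `tad-compare`, `gap-fraction`,
`simulate`, `run`.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
decisions and known limitations in detail.
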