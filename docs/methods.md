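# Methods

This note records the models, conventions and numerical choices behind
`concatmap`, and what the simulator does and does not emulate.

## Coordinates and conventions

All internal coordinates are 0-based half-open.  Conversions to 1-based
conventions (pairs text format, SAM POS) happen only in `concatmap.io`, on
serialization.  The representative contact position of an aligned segment is
its 5′-most mapped reference base: `ref_start` on the forward strand,
`ref_end − 1` on the reverse — the common pairs-format practice.  Mates of a
fully mapped pair are normalized to upper-triangle order (chrom1 ≤ chrom2 by
sort order, pos1 ≤ pos2 within a chromosome) so binning and deduplication are
deterministic.

## In silico digestion

An enzyme is a recognition motif (IUPAC codes) plus a top-strand cut offset
in `[0, len(motif)]`: DpnII `^GATC` (offset 0), HindIII `A^AGCTT` (offset 1),
NlaIII `CATG^` (offset 4).  Scanning advances one base at a time, so
overlapping occurrences (e.g. in `GATCGATC`) are all found.  An `N` in the
subject never matches any motif code: masked regions must not produce cut
sites.  For non-palindromic motifs the reverse complement is scanned as well,
with the bottom-strand cut at `match_start + len(motif) − cut_offset` in
top-strand coordinates.  Cut positions at 0 or at sequence length are
dropped (they would delimit empty segments), so `k` interior cuts always
yield `k + 1` segments that tile the read exactly.  No minimum segment
length is imposed by default; `digest_read(..., min_length=...)` makes the
choice explicit where a caller wants one.

## Pair expansion, filtering, duplicates

All C(n, 2) pairs are emitted per read, *including* pairs with unmapped
mates; the MAPQ filter removes them afterwards so rejection tallies are
observable and partition the input exactly (unmapped-mate takes precedence
over low-MAPQ in the tally).  The filter keeps a pair iff both mates are
mapped and `min(mapq1, mapq2) ≥ mapq_min`; the conventional threshold is 1.
Raising the threshold can only shrink the retained set (tested property).

Mock paired-end templates are one per contact pair: mate 1 takes up to
`mate_length` bases (default 150, the conventional short-read length) from
its segment's 5′ end; mate 2 takes the same slice of its segment,
reverse-complemented, giving FR orientation.  Mate coordinates are the
source segments' mapping coordinates.

PCR duplicates are detected by alignment fingerprint: the ordered tuple of
(chrom, ref_start, strand) over a read's segments.  The real workflow uses a
sequence-level deduplicator upstream of alignment; at desk scale the
alignment fingerprint is an equivalent, exactly testable criterion.  The
representative of a duplicate group is the first read id in sort order, so
the operation is idempotent and order-independent.

## Phase imputation

Within one concatemer read, segments derive from a single chromosomal fiber,
so phased segments overwhelmingly share one haplotype.  The imputation rule
is deliberately conservative: for each unphased mapped segment, the evidence
set is the read's *originally* phased segments on the same chromosome within
30 Mbp (inclusive) of the segment's representative position.  The segment is
tagged only when the evidence is non-empty (configurable minimum, default 1)
and unanimous.  Original tags are never modified, and newly imputed tags are
not evidence within the pass (no chaining), which makes the result
independent of processing order and guarantees an imputed tag never
contradicts any in-window phased segment.  The window is anchored per
unphased segment, not per read span.

Aggregate concordance is reported two ways, because the natural denominator
is ambiguous: the fraction of eligible reads (≥ 2 same-chromosome phased
segments) that are fully concordant, and the pooled fraction of agreeing
same-chromosome phased segment pairs.

## Contact matrices and Knight–Ruiz balancing

Contacts are binned over a genome-wide bin index (chromosomes in input
order, `ceil(L / bin_size)` bins each); each pair increments exactly one
unordered cell, so matrix mass equals pair count.  Preset resolutions are
2.5 Mbp and 50 kbp.

Balancing finds the diagonal scaling `W` with every non-masked row of
`W M W` summing to 1, via the inner–outer Newton/conjugate-gradient scheme
of the Knight–Ruiz algorithm.  Numerical choices:

- all-zero rows are masked before balancing;
- convergence is declared on the max-norm of the row-sum residual at
  `0.4 × tol` (default `tol = 1e-6`), which bounds the post-convergence
  row-sum dispersion `max/min − 1` strictly below `tol` — a 2-norm criterion
  would not;
- bins whose only contact is their own diagonal balance in closed form
  (`w = 1/√diag`);
- a matrix whose remaining bins split into two or more connected components
  of size ≥ 2 is rejected with status `disconnected` rather than balanced
  per block: isolated regions are a real failure mode of balancing on
  repeat-dense chromosomes, and the failure must be observable;
- non-convergence within the iteration budget returns status
  `not_converged`, never a silent result.

Matrix correlation is Pearson `r²` over upper-triangle cells defined in both
matrices.  Zero cells are included by default (the conservative choice — the
inclusion rule is otherwise a hidden degree of freedom); `cells="nonzero"`
restricts to cells nonzero in either matrix for exploring the alternative.

## TAD concordance

The measure of concordance between two domain partitions A and B is

    MoC = ( Σ_ij |A_i ∩ B_j|² / (|A_i| |B_j|) − 1 ) / ( √(N_A N_B) − 1 )

with MoC = 1 by convention when both partitions hold a single domain (the
formula is otherwise 0/0).  Only intervals labeled `domain` enter MoC and
the Jaccard indices; `boundary` and `gap` intervals are excluded because the
metric is defined over domain partitions.  Jaccard comes in two modes:
basepair Jaccard of domain territory (any overlap), and a stricter variant
counting a domain pair as matched only when each overlaps the other by
≥ 25% of its own length, reporting the Jaccard of matched territory.  Gap
cataloging reports, per annotation class, the percent of class basepairs
labeled `gap` — a coverage-quality measure for the domain caller.

MAPQ class profiles count *segments* (not reads) against BED classes with an
any-overlap (≥ 1 bp) rule, so one segment may count in several classes, at
the cutoff ladder {1, 10, 20, 30, 60}; percentages are non-increasing in the
cutoff by construction.

## The simulator

The generator produces the conditions the downstream statistics assume, with
exact ground truth:

- **Diploid genome** — haplotype 1 is uniform random ACGT; haplotype 2
  differs by substitutions drawn per base at the SNV rate (default `1e-3`,
  a typical human heterozygosity).  Substitution-only divergence keeps
  coordinates identical across haplotypes, so truth records are valid
  against either.
- **Segments per read** — shifted negative binomial (`1 + NB`) with
  dispersion 3 and the mean solved numerically so the distribution *median*
  hits the target (default 17, the observable a four-cutter concatemer
  library reports); a `fixed` family emits exactly *k* segments, used for
  decay calibration where two-segment reads give directly
  power-law-distributed pair distances.
- **Ligation model** — cohesive-end religation regenerates the recognition
  site, so a read is assembled as
  `motif[offset:] + core_1 + motif + core_2 + … + motif[:offset]`, each
  `core` a restriction fragment stripped of its boundary motif bases.
  Digestion of an error-free read therefore recovers the truth boundaries
  *exactly*, and each segment equals its source fragment (forward) or the
  reverse complement of the fragment interval shifted by
  `len(motif) − 2·offset` (the bottom strand of the filled-in sticky ends).
  The preset motifs have no period, so no spurious site can straddle a
  junction; the simulator re-digests every error-free read as an internal
  assertion.  Reverse orientation requires a palindromic motif (all three
  presets are).  Only interior fragments — flanked by genuine cut sites —
  enter the sampling universe, since terminal fragments lack a sticky end.
- **Contact geometry** — each read picks a haplotype uniformly and an anchor
  fragment uniformly; every further fragment is trans (uniform over other
  chromosomes) with probability `p_trans` (default 0.05), else sampled with
  probability ∝ `d^−α` over fragment-midpoint distance to the anchor
  (default α = 1, the classic contact-probability scaling), with self-pairs
  excluded and distances floored at one mean fragment length to avoid
  self-ligation artifacts.
- **Duplicates** — each read is duplicated with probability δ (default
  0.018) with provenance recorded.
- **Truth alignments** — `truth_to_alignments` stands in for a real aligner
  (MAPQ 60, or drawn from a supplied set to exercise filters; optional
  sparse haplotype tagging) so the whole chain runs deterministically and
  download-free.

What the simulator does *not* emulate, hence what passing tests do not show
about real data: sequencing error and chimeric artifacts (an error rate
knob exists but defaults to 0 and breaks exact invertibility), TAD and
compartment structure in the decay process (one global exponent),
enzyme-site density bias beyond what the random genome induces, mapping
ambiguity (truth alignments are perfect), and amplification bias.  Published
real-data statistics (median segment counts, phasing percentages,
matrix correlations against other assays) are properties of external
sequencing data and are not asserted against simulation.

## Problem sizes

Test and acceptance workloads are sized for a desk run: genomes of one to
two chromosomes at 0.15–3 Mbp, 40–50,000 reads per scenario, 200×200
balancing matrices.  Decay-exponent recovery uses 50,000 two-segment reads
on a 3-Mbp chromosome and fits the log–log slope over 5–300 kbp, well inside
the chromosome span so boundary truncation does not bias the estimate; the
recovered exponent lands within a few percent of the configured α.  On the
package's default small chromosomes every segment pair is within the 30-Mbp
window, so imputation saturates (the pipeline demo goes from ~26% to ~95%
segments phased); window behavior at scale is exercised by dedicated
boundary fixtures at 29,999,999 and 30,000,001 bp instead.

## Known limitations

- Alignment itself is out of scope: alignments are consumed (SAM/BAM with
  `readid:segindex` names, or the TSV dialect), never produced.
- Pair deduplication at restriction-fragment level across reads is not
  implemented (read-level fingerprints only).
- The pairs writer emits the 4DN text format only; binary containers
  (`.hic`, `.cool`) are out of scope.
- `filter_pairs` implements both-mapped + MAPQ; SAM proper-pair bitmask
  semantics beyond that are an extension point, not a behavior.
- KR balancing materializes dense per-chromosome matrices; fine for the
  bin counts this package targets, not for genome-wide 1-kbp bins.
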