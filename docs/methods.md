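# Methods

This note documents the models, algorithms and design choices behind
`asmgrade`: what each stage computes, which parameters matter, what the
synthetic fixtures do and do not emulate, and where the definitions are
this package's own.

## Coordinates and containers

All internal coordinates are 0-based half-open; the two external formats
that use 1-based inclusive coordinates (GFF3 and MUMmer `show-coords`) are
converted at their parser/writer boundaries and nowhere else. A reference
genome is an ordered map of id → uppercase sequence over {A,C,G,T,N};
IUPAC ambiguity codes are collapsed to N with a logged warning rather than
rejected, so real references parse. Scaffolds are split into contigs at
maximal N runs of length ≥ `min_n_run` (default 10, a common scaffolder
convention — the split rule itself is this package's definition); shorter
runs stay inside contigs, and contigs plus split runs reconstruct the
scaffold exactly.

## Read simulation

Reads are drawn fragment-wise: a reference sequence is chosen with
probability proportional to its length, an insert length from
N(mean, sd) truncated to [2 × read length, sequence length] and rounded,
the start uniform over valid placements, the strand uniform. Insert size
means the outer distance (mate-1 start to mate-2 end, both reads
inclusive), matching the usual library-prep meaning of paired-end spacing.
Mates are emitted in FR ("innie") orientation for all insert sizes;
mate-pair circularization artifacts (linkers, RF orientation) are not
modeled. The read count is ceil(coverage × genome length / read length),
rounded up to even for paired data, so emitted bases meet the requested
fold-coverage to within a read length.

Error models (defaults are this package's calibration choices, all
configurable):

* **Illumina**: the substitution probability ramps linearly along the read,
  p(i) = start + (end − start)·i/(L−1), defaults 0.1% at the 5′ end to
  1.0% at the 3′ end; no indels. The expected substitutions per read is
  the sum of the ramp (0.55 for L = 100 at the defaults), which the tests
  check against simulation.
* **454**: uniform substitutions at 0.1%; each maximal homopolymer run of
  length k ≥ 2 additionally receives a ±1-base indel of the run's
  nucleotide with probability min(1, 0.01·k), direction equiprobable. Reads
  keep their post-indel length (±1 per event) rather than being re-trimmed;
  the ground-truth edit list is the contract that matters downstream, and
  replaying it on the source substring must reproduce the emitted read
  byte-for-byte. 454 reads are fixed at 500 bp, not a length
  distribution — a documented simplification.

Qualities are a constant Q=30 placeholder (Sanger Phred+33): nothing in
the evaluation pipeline consumes qualities. One RNG per dataset is seeded
from the dataset spec; an A/B dataset pair uses seed and seed + 1. Output
is byte-identical for identical (reference, spec, seed).

## Assembly statistics

Nxx uses the "first length at which the cumulative sum of the descending
sort reaches the fraction of the total, with ≥" convention, stated
explicitly because conventions differ; the tests pin it against an
exhaustive prefix-scan oracle. Size-class counts (">1000 bp", ">5000 bp")
are strict inequalities, matching the printed symbol. N bases count toward
scaffold lengths; contig lengths exclude split N runs but include retained
short runs.

## Alignment acquisition

`show-coords` rows carry no per-event counts, so total error bases are
reconstructed as round((1 − identity) × alignment columns), the length
difference is taken as the indel floor (one event per base) and the
remainder as mismatches — a documented approximation that is exact for
the identity and error-rate totals but not for the mismatch/indel split
of indel-bearing blocks. PAF columns 10/11 give matches and column count;
a `cg:Z` CIGAR, when present, refines the split exactly. Both writers are
round-trip stable: parse∘write∘parse = parse.

The toy aligner exists so the whole pipeline is testable without external
binaries; it is a test-scale tool (guarded at 10 Mb of reference) and not
a substitute for nucmer/minimap2 at genome scale. It works in three steps
per query and strand:

1. **Anchors**: maximal exact matches ≥ `min_anchor` (default 21),
   obtained by merging consecutive k-mer hits per (reference, diagonal)
   from a reference k-mer index.
2. **Chaining**: greedy collinear chaining in query order. An anchor
   attaches to the compatible chain with the smallest combined query+
   reference gap (so chains do not hop between near-identical repeat
   copies), with both gaps ≤ 2,000 bases, progression required on both
   axes, overlap trimming capped at 50 bases (overlaps beyond that mean
   the anchor belongs to another chain), and no chaining across query N
   runs — scaffold gaps must surface as coverage holes, not be absorbed
   as alignment gaps.
3. **Gap closure**: inter-anchor gaps are closed by end-gap-free global
   alignment at unit costs (edlib), giving exact mismatch and indel
   counts from the CIGAR. A gap longer than 20 bases whose edit distance
   exceeds 0.3 × its length is declared unalignable and splits the chain:
   unrelated DNA aligns at a normalized distance near 0.47, homologous
   sequence far below, so 0.3 cleanly separates e.g. a short inverted
   segment from a divergent but homologous stretch.

Block identity is (columns − mismatches − indel bases) / columns with
columns = (ref span + query span + indel bases) / 2. Ties between
equal-scoring chains resolve to (lower reference start, then + strand)
through the deterministic output ordering.

## Fidelity evaluation

Blocks are filtered (identity ≥ 0.90, length ≥ 65 — both configurable)
and classified per query:

1. **Ambiguity**: two blocks contending for the same query bases (mutual
   overlap ≥ 50% of the longer block) with identities within the
   ambiguity margin (default 0.02) mark their shared bases contested —
   unless a clearly better block (identity higher by at least the margin)
   covers the same span. A query whose contested bases reach the
   95% threshold is AMBIGUOUS; its blocks are excluded from coverage by
   default (`include_ambiguous` flips this). "Ambiguously aligned bases"
   (repeat-contested) are distinct from "ambiguous bases" (N characters
   in the assembly consensus); both are reported.
2. **Tiling**: greedy selection by identity × length; a block is kept when
   at least half of its query span adds new coverage. Optimal chaining was
   rejected for simplicity at test scale; the greedy choice can in
   principle differ from the optimum on pathological overlap structures.
3. **Breakpoint walk** over kept blocks in query order: reference change →
   translocation; strand flip → inversion; |reference gap − query gap| >
   `relocation_threshold` (default 1,000 bases) or reference order
   reversal → relocation. Any breakpoint marks the query MISASSEMBLED;
   otherwise ALIGNED, or PARTIAL below 95% aligned query bases. The walk
   itself is this package's operational definition of misassembly — the
   original study reported misassembly counts without publishing a
   detection algorithm, and this is the definition later evaluation tools
   converged on.

Representation is computed from the union of kept blocks' reference
intervals intersected with the (merged) region; because region members are
merged before forming the denominator, representation cannot exceed 1.
Error rates are events per 100 kb of aligned reference (the denominator is
per-block reference overlap with the region; the scale is configurable to
a per-base fraction — the original study never stated its denominator).
Blocks carry no within-block event positions, so events are apportioned to
a region by the block's overlap fraction, a documented approximation that
is exact when blocks lie entirely inside or outside the region.
Misassembly rate is breakpoints per 100 kb of aligned reference;
a breakpoint is attributed to a region when either flanking block
intersects it.

Gap accounting: gaps are maximal uncovered reference intervals clipped to
the region (so covered + gap bases = region length exactly, per region — a
conservation law the tests assert); captured gaps are holes whose
immediate flanking blocks come from one scaffold in consistent order and
strand; negative gaps are reference overlaps between consecutive kept
blocks of one query; internal gaps/overlaps are the query-coordinate
analogues.

Per-contig quantities that have no regional meaning — unaligned contigs
and bases, assembly N count, ambiguously-aligned counts — are
assembly-global and repeated on every region row. Evaluation is
scaffold-level by default (matching how the original pipeline aligned
scaffold assemblies); contig-level mode is available behind a flag.

## Synthetic fixtures

The genome builder plants dispersed near-identical repeat-family copies
(divergence by uniform random substitution only — indel divergence is
excluded so ground truth stays exact) and toy gene annotations in a
random background at a chosen GC (default 0.43, plant-like). The
corruption builder cuts the reference into scaffolds and applies
substitutions, small indels, inversions, excise-and-reinsert relocations,
cross-sequence splices, dropped intervals (uncaptured gaps) and N-run
replacements (captured gaps). Its ground truth is derived from the
resulting piece order with the same adjacency rules the fidelity engine
applies to alignment blocks — breakpoints are counted per block adjacency
— so tests can assert exact equality rather than approximate agreement.

The randomized fixture generator keeps edits isolated: point edits sit
≥ 100 bases from any block boundary and repeat copy, structural segments
exceed the aligner's 2,000-base chain-gap limit so junctions cannot be
absorbed as alignment gaps, and translocation donor edges are chosen so
their first flanking base differs from the insertion context (otherwise an
exact-match aligner legitimately extends one base past the planted
junction and the coverage truth would be stale by one base).

What the fixtures do **not** emulate: realistic transposon structure,
polyploidy or segmental duplication, sequencing-coverage-driven contig
breaks, assembler consensus errors correlated with coverage, or indel
divergence inside repeat families. Passing the planted-defect battery
shows the measurement machinery is exact on isolated, well-separated
defects; it does not certify behavior on dense or interacting defects,
where blocks merge and any evaluator's attribution becomes
definition-dependent.

## Problem sizes and numerical choices

The test battery uses 30 kb fixture genomes (200 randomized draws), a
100 kb identity genome, and a 200 kb genome for the miniature two-dataset
study (75 bp reads, 2 kb insert at 16x plus 8 kb insert at 24x — the A/B
design at 40x total); these sizes exercise every code path while keeping
the full suite fast on a single CPU. Averages report 0 when the count is
0; rates report 0 (with zero aligned bases) rather than dividing by zero;
empty alignment sets yield a valid all-zero record with representation 0.

## Persistence

Runs are stored one flat row per (run, genome region) with the run
metadata (dataset ids, assembler, parameters, k value, resource fields —
nullable, since no assembler is bundled; they are recorded only if the
user wraps an assembler invocation), the assembly-statistics block, and
the metric fields. TSV, JSON and SQLite are interchangeable and lossless
(SQLite replaces a server database with the same relational shape; the
DDL ships as `asmgrade.reporting.SCHEMA_DDL`). `compare_runs` reports
mean, sample sd (null for single-member groups) and n per group;
plots are static bar charts rather than an interactive tool.
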