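# asmgrade

Simulate sequencing reads, grade genome assemblies.

`asmgrade` is a self-contained toolkit for planning and evaluating de novo
genome sequencing strategies, aimed at researchers deciding how to sequence
a genome (platform, read length, coverage, paired-end insert sizes) and at
anyone who needs to measure how faithful an assembly is to a known
reference. It covers the three stages of a simulated sequencing study:

1. **Read simulation** — platform-specific paired-end or fragment reads
   (454-style 500 bp reads; Illumina-style 50/75/100 bp reads) with
   platform-tailored error models, drawn from a reference genome at a
   requested fold-coverage and insert geometry, with a ground-truth
   placement table for every read.
2. **Assembly statistics** — the contig/scaffold block: counts, total and
   average lengths, largest lengths, size-class counts (>1000 bp,
   >5000 bp), and N50.
3. **Fidelity metrics** — alignment-derived measures obtained by comparing
   the assembly against the reference: representation, mismatch and indel
   error rates, misassembly detection, ambiguous-alignment accounting, and
   gap/captured-gap accounting — for the whole genome and restricted to
   annotated regions (genes, repeats, protein-family coding sequences) from
   a GFF3 file.

Alignments can come from MUMmer (`nucmer -o -p <base> <ref> <assembly>`,
parsed from `show-coords` text), from any PAF producer such as minimap2, or
from the built-in exact-anchor toy aligner, which makes the whole pipeline
runnable at test scale with no external binaries.

## The core quantities

With `A` the set of kept alignment blocks of the assembly against reference
region `R` (intervals merged):

* **Representation** = |⋃ blocks ∩ R| / |R| — the fraction of the region
  covered by the assembly.
* **Mismatch / indel / error rate** = events per 100 kb of aligned
  reference within `R`; error rate = mismatch rate + indel rate exactly.
* **N50** = the first length, scanning scaffold (or contig) lengths in
  descending order, at which the cumulative sum reaches half the total.
* **Misassembly** — consecutive alignment blocks of one scaffold, in query
  order, that are discordant on the reference: a reference-sequence change
  (*translocation*), a strand flip (*inversion*), or a gap disagreement
  beyond a threshold / reference-order reversal (*relocation*, default
  threshold 1,000 bases).
* **Gap** = a maximal uncovered reference interval; a **captured gap** is
  spanned by a single scaffold (flanking blocks from the same scaffold in
  consistent order, typically across an N run); a **negative gap** is a
  reference overlap between consecutive blocks of one query.

## Worked example

Generate a corrupted synthetic fixture (a 30 kb genome cut into scaffolds
with planted substitutions, indels, a relocation and inversions) and
evaluate it end to end:

```console
$ asmgrade fixture fx --preset corrupted --seed 7
fixture written to fx
$ cat fx/truth.tsv
mismatches      4
indel_events    1
relocations     3
inversions      2
translocations  0
$ asmgrade evaluate --ref fx/ref.fasta --assembly fx/assembly.fasta --gff fx/regions.gff3
genome_region  representation  error_rate  mismatch_rate  indel_rate  misassembly_rate  n_gaps  n_captured_gaps
          all          0.9815   16.979658      13.583727    3.395932         16.979658       1                0
         gene          1.0000   16.238216      16.238216    0.000000         52.668539       0                0
       repeat          1.0000   17.167473      17.167473    0.000000        166.666667       0                0
```

Reading the `all` row: the assembly covers 98.15% of the genome (one
uncovered interval — the planted dropped segment); 4 mismatches over
~29.5 kb of aligned reference give 13.58 mismatches per 100 kb and the one
planted indel gives 3.40; the five breakpoint-inducing edits (3 relocation
junctions + 2 inversion junctions) give a misassembly rate of 16.98 per
100 kb. The `gene`/`repeat` rows restrict the same metrics to annotated
regions.

Simulating reads is just as direct:

```bash
asmgrade simulate ref.fasta out/dsA --platform illumina --read-length 75 \
    --coverage 16 --insert 2000 --seed 1
```

which writes `dsA_1.fastq`, `dsA_2.fastq` and `dsA_truth.tsv` (read id,
source position, strand, injected edits).

Evaluation runs are persisted in a flat relational schema (TSV, JSON or
SQLite) and aggregated with `asmgrade report --db runs.sqlite
--group-by assembler --metric representation`.

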