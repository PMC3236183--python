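"""Platform-specific simulated read generation.

Generates 454-style (long, homopolymer-indel-prone) and Illumina-style
(short, 3'-biased substitution) reads from a reference genome, as fragment
or paired-end FR ("innie") datasets, with a ground-truth placement and edit
table written alongside the FASTQ so every downstream metric is testable.

Error-model defaults are this package's own calibration choices, exposed in
:class:`ErrorModelParams` and configurable throughout:

* Illumina: substitution probability ramps linearly from 0.1% at the 5' end
  to 1.0% at the 3' end of the read; no indels.
* 454: uniform substitutions at 0.1%; additionally each maximal homopolymer
  run of length k >= 2 suffers a +/-1-base indel of the run's nucleotide with
  probability min(1, 0.01 * k).

Insert size is the outer distance, mate-1 start to mate-2 end, both reads
inclusive. Qualities are a constant Q=30 placeholder (nothing downstream
consumes them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .sequence_io import ReferenceGenome, reverse_complement

Platform = Literal["LS454", "ILLUMINA"]

_BASES = "ACGT"
_ALT = {b: _BASES.replace(b, "") for b in _BASES}
_Q30 = "?"  # Phred+33 for Q=30

TRUTH_HEADER = ["read_id", "ref_id", "start", "strand", "edits"]


@dataclass
class ErrorModelParams:
    """Per-platform error probabilities.

    ``illumina_sub_rate_start``/``_end`` give the substitution probability at
    the first and last read position; the rate ramps linearly in between.
    ``ls454_base_sub_rate`` is a uniform per-base substitution probability.
    ``ls454_homopolymer_slope`` is the per-run-base increment of the indel
    probability assigned to each maximal homopolymer run (k >= 2).
    """

    illumina_sub_rate_start: float = 0.001
    illumina_sub_rate_end: float = 0.010
    ls454_base_sub_rate: float = 0.001
    ls454_homopolymer_slope: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "illumina_sub_rate_start",
            "illumina_sub_rate_end",
            "ls454_base_sub_rate",
            "ls454_homopolymer_slope",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def zero(cls) -> "ErrorModelParams":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class ReadDatasetSpec:
    """One simulated dataset: platform, geometry, coverage and error model."""

    platform: Platform = "ILLUMINA"
    read_length: int = 75
    paired: bool = True
    insert_mean: float = 2000.0
    insert_sd: float | None = None  # default: 10% of the mean
    coverage: float = 40.0
    seed: int = 0
    error_params: ErrorModelParams = field(default_factory=ErrorModelParams)
    name: str = "ds"

    def __post_init__(self) -> None:
        if self.platform not in ("LS454", "ILLUMINA"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.paired:
            if self.insert_mean < 2 * self.read_length:
                raise ValueError(
                    f"insert_mean {self.insert_mean} < 2 x read_length "
                    f"{self.read_length}"
                )
            if self.platform == "LS454" and self.insert_mean < 2000:
                raise ValueError(
                    "inserts below 2000 bp are an Illumina-only geometry"
                )
        if self.insert_sd is None:
            self.insert_sd = 0.1 * self.insert_mean


@dataclass
class SimulatedRead:
    """One emitted read with its ground-truth placement and edit list.

    ``start`` is the 0-based reference start of the *unmutated* source
    substring; ``edits`` are (position, from, to) triples in read coordinates
    applied to that substring after strand orientation (so replaying them on
    the oriented truth substring reproduces ``sequence`` exactly). Indel
    edits use from="-" for insertions and to="-" for deletions.
    """

    id: str
    sequence: str
    ref_id: str
    start: int
    strand: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)


def plan_dataset(spec: ReadDatasetSpec, genome_length: int) -> int:
    """Number of reads needed for the requested fold-coverage.

    Coverage means total read bases / genome length; n = ceil(cov * G / L),
    rounded up to even for paired datasets.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n = math.ceil(spec.coverage * genome_length / spec.read_length)
    if spec.paired and n % 2:
        n += 1
    return n


def sample_insert(
    spec: ReadDatasetSpec, ref: ReferenceGenome, rng: np.random.Generator
) -> tuple[str, int, int, str]:
    """Draw one fragment placement: (ref_id, start, insert_length, strand).

    The reference sequence is chosen with probability proportional to its
    length; the insert length is normal(mean, sd) truncated to
    [2*read_length, sequence length]; the start is uniform over valid
    placements and the strand uniform. For fragment (unpaired) datasets the
    "insert" is the read itself.
    """
    min_insert = 2 * spec.read_length if spec.paired else spec.read_length
    required = max(min_insert, int(spec.insert_mean)) if spec.paired else min_insert
    ids = [sid for sid in ref if len(ref[sid]) >= required]
    if not ids:
        raise ValueError(
            f"no reference sequence is >= the minimum insert of {required} bp"
        )
    lens = np.array([len(ref[sid]) for sid in ids], dtype=float)
    sid = ids[rng.choice(len(ids), p=lens / lens.sum())]
    seq_len = len(ref[sid])
    if spec.paired:
        ins = float(rng.normal(spec.insert_mean, spec.insert_sd))
        ins = int(round(min(max(ins, min_insert), seq_len)))
    else:
        ins = spec.read_length
    start = int(rng.integers(0, seq_len - ins + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return sid, start, ins, strand


def _ramp(params: ErrorModelParams, length: int) -> np.ndarray:
    if length == 1:
        return np.array([params.illumina_sub_rate_start])
    return np.linspace(
        params.illumina_sub_rate_start, params.illumina_sub_rate_end, length
    )


def expected_illumina_subs(params: ErrorModelParams, length: int) -> float:
    """Closed-form expected substitutions per read: sum of the ramp."""
    return float(_ramp(params, length).sum())


def apply_illumina_errors(
    sequence: str, params: ErrorModelParams, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate a read with the position-ramped substitution model.

    Position i (0-based, read length L) is substituted with probability
    p(i) = start + (end - start) * i / (L - 1), target uniform over the three
    alternative bases; N positions are never mutated.
    """
    p = _ramp(params, len(sequence))
    hits = np.nonzero(rng.random(len(sequence)) < p)[0]
    if hits.size == 0:
        return sequence, []
    out = list(sequence)
    edits: list[tuple[int, str, str]] = []
    for i in hits:
        base = out[i]
        if base == "N":
            continue
        alt = _ALT[base][rng.integers(0, 3)]
        out[i] = alt
        edits.append((int(i), base, alt))
    return "".join(out), edits


def _homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] != "N":
            runs.append((i, j))
        i = j
    return runs


def apply_454_errors(
    sequence: str, params: ErrorModelParams, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate a read with the 454-style model.

    Uniform substitutions at ``ls454_base_sub_rate``; each maximal
    homopolymer run of length k >= 2 additionally receives a +/-1-base indel
    of the run's nucleotide with probability min(1, k * slope), direction
    equiprobable. The read keeps its native (possibly +/-1) length; edit
    positions refer to the pre-indel substituted sequence.
    """
    out = list(sequence)
    edits: list[tuple[int, str, str]] = []
    if params.ls454_base_sub_rate > 0:
        hits = np.nonzero(rng.random(len(out)) < params.ls454_base_sub_rate)[0]
        for i in hits:
            base = out[i]
            if base == "N":
                continue
            alt = _ALT[base][rng.integers(0, 3)]
            out[i] = alt
            edits.append((int(i), base, alt))
    substituted = "".join(out)
    # indels applied right-to-left so earlier positions stay valid
    indels: list[tuple[int, str, str]] = []
    for start, end in reversed(_homopolymer_runs(substituted)):
        k = end - start
        p = min(1.0, k * params.ls454_homopolymer_slope)
        if rng.random() < p:
            base = substituted[start]
            if rng.random() < 0.5:  # insertion
                out.insert(end, base)
                indels.append((end, "-", base))
            else:  # deletion
                del out[end - 1]
                indels.append((end - 1, base, "-"))
    edits.extend(reversed(indels))
    return "".join(out), edits


def apply_edits(truth_substring: str, edits: list[tuple[int, str, str]]) -> str:
    """Replay an edit list onto the oriented truth substring.

    Substitutions first (positions in original coordinates), then indels in
    the recorded order (positions in substituted-sequence coordinates,
    right-to-left as emitted by the 454 model).
    """
    out = list(truth_substring)
    subs = [(i, a, b) for i, a, b in edits if a != "-" and b != "-"]
    indels = [(i, a, b) for i, a, b in edits if a == "-" or b == "-"]
    for i, a, b in subs:
        if out[i] != a:
            raise ValueError(f"edit mismatch at {i}: expected {a}, found {out[i]}")
        out[i] = b
    for i, a, b in sorted(indels, key=lambda e: -e[0]):
        if a == "-":
            out.insert(i, b)
        else:
            if out[i] != a:
                raise ValueError(f"deletion mismatch at {i}")
            del out[i]
    return "".join(out)


def _mutate(
    seq: str, spec: ReadDatasetSpec, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    if spec.platform == "ILLUMINA":
        return apply_illumina_errors(seq, spec.error_params, rng)
    return apply_454_errors(seq, spec.error_params, rng)


def generate_reads(
    ref: ReferenceGenome, spec: ReadDatasetSpec
) -> Iterator[SimulatedRead]:
    """Yield the dataset's reads (pairs interleaved mate1, mate2)."""
    genome_length = ref.total_length
    n_reads = plan_dataset(spec, genome_length)
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    if spec.paired:
        for pair_idx in range(n_reads // 2):
            sid, start, ins, strand = sample_insert(spec, ref, rng)
            frag = ref[sid][start : start + ins]
            if strand == "-":
                frag = reverse_complement(frag)
            # mate 1 from the 5' end of the fragment, mate 2 reverse-
            # complemented from the 3' end (FR orientation)
            m1 = frag[:L]
            m2 = reverse_complement(frag[-L:])
            if strand == "+":
                s1, st1 = start, "+"
                s2, st2 = start + ins - L, "-"
            else:
                s1, st1 = start + ins - L, "-"
                s2, st2 = start, "+"
            for mate, seq_, s_, st_ in ((1, m1, s1, st1), (2, m2, s2, st2)):
                mutated, edits = _mutate(seq_, spec, rng)
                yield SimulatedRead(
                    id=f"{spec.name}_p{pair_idx}/{mate}",
                    sequence=mutated,
                    ref_id=sid,
                    start=s_,
                    strand=st_,
                    edits=edits,
                )
    else:
        for i in range(n_reads):
            sid, start, ins, strand = sample_insert(spec, ref, rng)
            frag = ref[sid][start : start + ins]
            if strand == "-":
                frag = reverse_complement(frag)
            mutated, edits = _mutate(frag, spec, rng)
            yield SimulatedRead(
                id=f"{spec.name}_f{i}",
                sequence=mutated,
                ref_id=sid,
                start=start,
                strand=strand,
                edits=edits,
            )


def _fmt_edits(edits: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{i}:{a}>{b}" for i, a, b in edits) or "."


def parse_edits(text: str) -> list[tuple[int, str, str]]:
    if text == ".":
        return []
    out = []
    for tok in text.split(";"):
        pos, _, change = tok.partition(":")
        a, _, b = change.partition(">")
        out.append((int(pos), a, b))
    return out


def simulate(
    ref: ReferenceGenome, spec: ReadDatasetSpec, out_prefix: str | Path
) -> dict[str, Path]:
    """Write the dataset to FASTQ plus a ground-truth TSV.

    Paired datasets produce ``<prefix>_1.fastq``/``<prefix>_2.fastq`` with
    synchronized /1 and /2 mate naming; fragment datasets one
    ``<prefix>.fastq``. ``<prefix>_truth.tsv`` records id, placement, strand
    and the injected edit list for every read. Output is byte-identical for
    identical (reference, spec, seed).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_path = out_prefix.parent / f"{out_prefix.name}_truth.tsv"
    paths["truth"] = truth_path

    def fastq_entry(read: SimulatedRead) -> str:
        return f"@{read.id}\n{read.sequence}\n+\n{_Q30 * len(read.sequence)}\n"

    with open(truth_path, "w") as truth:
        truth.write("\t".join(TRUTH_HEADER) + "\n")
        if spec.paired:
            p1 = out_prefix.parent / f"{out_prefix.name}_1.fastq"
            p2 = out_prefix.parent / f"{out_prefix.name}_2.fastq"
            paths["fastq_1"], paths["fastq_2"] = p1, p2
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for read in generate_reads(ref, spec):
                    fh = f1 if read.id.endswith("/1") else f2
                    fh.write(fastq_entry(read))
                    truth.write(
                        f"{read.id}\t{read.ref_id}\t{read.start}\t"
                        f"{read.strand}\t{_fmt_edits(read.edits)}\n"
                    )
        else:
            p = out_prefix.parent / f"{out_prefix.name}.fastq"
            paths["fastq"] = p
            with open(p, "w") as fh:
                for read in generate_reads(ref, spec):
                    fh.write(fastq_entry(read))
                    truth.write(
                        f"{read.id}\t{read.ref_id}\t{read.start}\t"
                        f"{read.strand}\t{_fmt_edits(read.edits)}\n"
                    )
    return paths


def make_ab_pair(
    spec_a: ReadDatasetSpec, spec_b: ReadDatasetSpec, seed: int
) -> tuple[ReadDatasetSpec, ReadDatasetSpec]:
    """Seed an A/B dataset pair from one base seed (A gets seed, B seed+1)."""
    return (
        replace(spec_a, seed=seed, name=spec_a.name or "A"),
        replace(spec_b, seed=seed + 1, name=spec_b.name or "B"),
    )
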