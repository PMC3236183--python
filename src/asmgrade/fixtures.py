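"""Synthetic genomes, annotations and deliberately corrupted assemblies.

Every metric in the package is testable without downloads: a seeded genome
builder plants repeat families and toy gene annotations, and a corruption
builder cuts the reference into scaffolds and applies substitutions,
indels, inversions, relocations, cross-sequence splices, dropped intervals
and N-run replacements — while deriving a machine-readable ground truth
with the *same* block-adjacency walk the fidelity engine uses, so tests can
assert exact equality rather than approximate agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fidelity_metrics import (
    Interval,
    RegionMap,
    interval_total,
    merge_intervals,
    subtract_intervals,
)
from .sequence_io import (
    AssemblySet,
    ReferenceGenome,
    Region,
    reverse_complement,
    split_scaffolds,
)

_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "N"}


@dataclass
class GenomePlan:
    """Recipe for a seeded toy genome.

    ``repeat_blocks`` are (copy_length, n_copies, divergence) families
    planted as dispersed near-identical copies; ``gene_density`` is genes
    per 10 kb. ``extra_sequences`` adds plain (feature-free) sequences named
    chr2, chr3, ... — handy as splice donors for translocation fixtures.
    Divergence within a family is uniform random substitution at the stated
    fraction (no indel divergence, keeping ground truth exact).
    """

    length: int = 100_000
    gc: float = 0.43
    repeat_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    gene_density: float = 1.0
    seed: int = 0
    extra_sequences: list[int] = field(default_factory=list)


@dataclass
class CorruptionPlan:
    """Edits applied to one reference sequence when building an assembly.

    Coordinates are 0-based on ``seq_id`` (default: the first reference
    sequence). ``indels`` are (position, +n) insertions / (position, -n)
    deletions; ``relocations`` are (start, end, new_position) excise-and-
    reinsert moves within one scaffold; ``translocations`` are
    (donor_seq_id, start, end, insert_position) splices from another
    sequence; ``n_run_insertions`` replace a reference interval with an
    equal-length N run (the captured-gap generator); ``dropped_intervals``
    are left out of the assembly entirely (their bounds become scaffold
    cuts). All edit zones must be pairwise non-overlapping.
    """

    seq_id: str | None = None
    substitutions: list[int] = field(default_factory=list)
    indels: list[tuple[int, int]] = field(default_factory=list)
    inversions: list[tuple[int, int]] = field(default_factory=list)
    relocations: list[tuple[int, int, int]] = field(default_factory=list)
    dropped_intervals: list[tuple[int, int]] = field(default_factory=list)
    n_run_insertions: list[tuple[int, int]] = field(default_factory=list)
    translocations: list[tuple[str, int, int, int]] = field(default_factory=list)
    seed: int = 0  # content of inserted bases


@dataclass
class GroundTruth:
    """What a faithful evaluator must measure on the corrupted assembly."""

    n_mismatch: int = 0
    n_indel_events: int = 0
    n_indel_bases: int = 0
    n_relocations: int = 0
    n_inversions: int = 0
    n_translocations: int = 0
    misassembled_scaffolds: set[str] = field(default_factory=set)
    uncovered: RegionMap = field(default_factory=dict)
    captured: RegionMap = field(default_factory=dict)

    @property
    def n_breakpoints(self) -> int:
        return self.n_relocations + self.n_inversions + self.n_translocations


# ---------------------------------------------------------------------------
# Genome builder
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _place(
    rng: np.random.Generator,
    occupied: list[Interval],
    length: int,
    genome_length: int,
    margin: int = 50,
    tries: int = 500,
) -> Interval:
    """Pick a slot of ``length`` not overlapping any occupied interval."""
    merged = merge_intervals(occupied)
    for _ in range(tries):
        start = int(rng.integers(margin, genome_length - length - margin))
        iv = (start - margin, start + length + margin)
        if not any(s < iv[1] and iv[0] < e for s, e in merged):
            return (start, start + length)
    raise ValueError("infeasible packing: could not place a planted feature")


def make_toy_genome(plan: GenomePlan) -> tuple[ReferenceGenome, list[Region]]:
    """Build a seeded random genome with planted repeats and toy genes.

    Returns the reference and the GFF-style region list (classes ``repeat``
    and ``gene``; 1-based inclusive coordinates). Deterministic under
    ``plan.seed``.
    """
    if not 0.0 < plan.gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(plan.seed)
    seq = _random_seq(rng, plan.length, plan.gc)
    occupied: list[Interval] = []
    regions: list[Region] = []

    for copy_len, n_copies, divergence in plan.repeat_blocks:
        master = _random_seq(rng, copy_len, plan.gc)
        for _ in range(n_copies):
            start, end = _place(rng, occupied, copy_len, plan.length)
            copy = master.copy()
            n_div = rng.binomial(copy_len, divergence)
            for pos in rng.choice(copy_len, size=n_div, replace=False):
                copy[pos] = _ROTATE[copy[pos].decode()].encode()
            seq[start:end] = copy
            occupied.append((start, end))
            regions.append(Region("chr1", start + 1, end, "repeat"))

    n_genes = int(round(plan.gene_density * plan.length / 10_000))
    for _ in range(n_genes):
        gene_len = int(rng.integers(500, 3001))
        start, end = _place(rng, occupied, gene_len, plan.length)
        occupied.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        regions.append(Region("chr1", start + 1, end, "gene", strand))

    sequences = {"chr1": b"".join(seq).decode()}
    for i, extra_len in enumerate(plan.extra_sequences, start=2):
        sequences[f"chr{i}"] = b"".join(
            _random_seq(rng, extra_len, plan.gc)
        ).decode()
    regions.sort(key=lambda r: (r.seq_id, r.start, r.end))
    return ReferenceGenome(sequences), regions


# ---------------------------------------------------------------------------
# Corruption builder
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    """One scaffold constituent: a reference segment or an N run."""

    kind: str  # "seq" | "N"
    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


def _zones(plan: CorruptionPlan) -> list[Interval]:
    zones: list[Interval] = [(p, p + 1) for p in plan.substitutions]
    zones += [(p, p + max(1, -n)) for p, n in plan.indels]
    zones += list(plan.inversions)
    zones += [(s, e) for s, e, _ in plan.relocations]
    zones += list(plan.dropped_intervals)
    zones += list(plan.n_run_insertions)
    return zones


def corrupt_assembly(
    ref: ReferenceGenome,
    plan: CorruptionPlan,
    scaffold_cuts: Sequence[int],
    relocation_threshold: int = 1000,
    min_n_run: int = 10,
) -> tuple[AssemblySet, GroundTruth]:
    """Cut the reference into scaffolds and apply the corruption plan.

    Ground truth is derived from the resulting piece order with the same
    adjacency rules the fidelity engine applies to alignment blocks, so an
    exact-equality comparison is meaningful. Overlapping edit zones are a
    hard error.
    """
    primary = plan.seq_id or next(iter(ref))
    length = len(ref[primary])
    rng = np.random.default_rng(plan.seed)

    zones = sorted(_zones(plan))
    for (s1, e1), (s2, e2) in zip(zones, zones[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping edit zones [{s1},{e1}) and [{s2},{e2})")
    for s, e in zones:
        if not 0 <= s < e <= length:
            raise ValueError(f"edit zone [{s},{e}) outside the reference")

    cuts = {0, length} | {int(c) for c in scaffold_cuts}
    for s, e in plan.dropped_intervals:
        cuts |= {s, e}
    boundaries = sorted(cuts)
    dropped = merge_intervals(plan.dropped_intervals)

    def is_dropped(a: int, b: int) -> bool:
        return any(s <= a and b <= e for s, e in dropped)

    scaffold_ivs = [
        (a, b)
        for a, b in zip(boundaries, boundaries[1:])
        if b > a and not is_dropped(a, b)
    ]

    def scaffold_of(pos: int, end_ok: bool = False) -> Interval:
        for a, b in scaffold_ivs:
            if a <= pos < b or (end_ok and pos == b):
                return (a, b)
        raise ValueError(f"position {pos} falls in no scaffold")

    # each in-scaffold edit zone must sit inside a single scaffold
    for s, e in plan.inversions + [(s, e) for s, e, _ in plan.relocations] + list(
        plan.n_run_insertions
    ):
        a, b = scaffold_of(s)
        if e > b:
            raise ValueError(f"edit zone [{s},{e}) crosses a scaffold cut at {b}")

    # split points per scaffold
    split_points: dict[Interval, set[int]] = {iv: {iv[0], iv[1]} for iv in scaffold_ivs}
    for s, e in plan.inversions + list(plan.n_run_insertions):
        iv = scaffold_of(s)
        split_points[iv] |= {s, e}
    for s, e, new_pos in plan.relocations:
        iv = scaffold_of(s)
        split_points[iv] |= {s, e}
        iv2 = scaffold_of(new_pos, end_ok=True)
        if iv2 != iv:
            raise ValueError("relocation target must stay within the scaffold")
        split_points[iv] |= {new_pos}
    for _, _, _, ins in plan.translocations:
        iv = scaffold_of(ins, end_ok=True)
        if ins not in range(iv[0], iv[1] + 1):
            raise ValueError("translocation insert outside scaffolds")
        split_points[iv] |= {ins}

    inversion_set = set(map(tuple, plan.inversions))
    n_run_set = set(map(tuple, plan.n_run_insertions))
    reloc_by_seg = {(s, e): new_pos for s, e, new_pos in plan.relocations}

    scaffolds: dict[str, list[_Piece]] = {}
    for idx, (a, b) in enumerate(scaffold_ivs):
        pts = sorted(split_points[(a, b)])
        pieces: list[_Piece] = []
        for s, e in zip(pts, pts[1:]):
            if s == e:
                continue
            if (s, e) in n_run_set:
                pieces.append(_Piece("N", primary, s, e))
            elif (s, e) in inversion_set:
                pieces.append(_Piece("seq", primary, s, e, "-"))
            else:
                pieces.append(_Piece("seq", primary, s, e))
        # relocations: excise, reinsert before the piece starting at new_pos
        for (s, e), new_pos in reloc_by_seg.items():
            if not (a <= s < b):
                continue
            seg = [p for p in pieces if p.start == s and p.end == e]
            if len(seg) != 1:
                raise ValueError(f"relocation segment [{s},{e}) not found intact")
            pieces.remove(seg[0])
            at = next(
                (i for i, p in enumerate(pieces) if p.start == new_pos), len(pieces)
            )
            pieces.insert(at, seg[0])
        # translocations: splice donor segments in
        for donor, ds, de, ins in plan.translocations:
            if not (a <= ins <= b):
                continue
            if donor not in ref or not 0 <= ds < de <= len(ref[donor]):
                raise ValueError(f"bad translocation donor segment {donor}:{ds}-{de}")
            at = next(
                (i for i, p in enumerate(pieces) if p.start == ins and p.ref_id == primary),
                len(pieces),
            )
            pieces.insert(at, _Piece("seq", donor, ds, de))
        scaffolds[f"scaffold_{idx}"] = pieces

    # materialize sequences with point edits
    subs_sorted = sorted(plan.substitutions)
    indels_sorted = sorted(plan.indels)

    def materialize(piece: _Piece) -> str:
        if piece.kind == "N":
            return "N" * len(piece)
        chars = list(ref[piece.ref_id][piece.start : piece.end])
        if piece.ref_id == primary and piece.strand == "+":
            for p in subs_sorted:
                if piece.start <= p < piece.end:
                    chars[p - piece.start] = _ROTATE[chars[p - piece.start]]
            for p, n in sorted(indels_sorted, key=lambda x: -x[0]):
                if piece.start <= p < piece.end:
                    off = p - piece.start
                    if n > 0:
                        ins = "".join(
                            "ACGT"[i] for i in rng.integers(0, 4, size=n)
                        )
                        chars[off:off] = list(ins)
                    else:
                        if p - n > piece.end:
                            raise ValueError(f"deletion at {p} crosses piece end")
                        del chars[off : off - n]
        seq = "".join(chars)
        return reverse_complement(seq) if piece.strand == "-" else seq

    asm = {
        sid: "".join(materialize(p) for p in pieces)
        for sid, pieces in scaffolds.items()
        if pieces
    }
    assembly = split_scaffolds(AssemblySet(scaffolds=asm), min_n_run)

    # ---- ground truth from the piece walk -------------------------------
    truth = GroundTruth(
        n_mismatch=len(plan.substitutions),
        n_indel_events=len(plan.indels),
        n_indel_bases=sum(abs(n) for _, n in plan.indels),
    )
    covered: dict[str, list[Interval]] = {}
    captured: dict[str, list[Interval]] = {}
    for sid, pieces in scaffolds.items():
        merged: list[_Piece] = []
        pending_n = 0
        n_gaps_between: list[int] = []  # query N bases before merged[i] (i>=1)
        for p in pieces:
            if p.kind == "N":
                pending_n += len(p)
                continue
            covered.setdefault(p.ref_id, []).append((p.start, p.end))
            if (
                merged
                and pending_n == 0
                and merged[-1].ref_id == p.ref_id
                and merged[-1].strand == p.strand == "+"
                and merged[-1].end == p.start
            ):
                merged[-1] = _Piece("seq", p.ref_id, merged[-1].start, p.end)
            else:
                merged.append(_Piece(p.kind, p.ref_id, p.start, p.end, p.strand))
                n_gaps_between.append(pending_n)
            pending_n = 0
        for (left, right), qgap in zip(zip(merged, merged[1:]), n_gaps_between[1:]):
            kind = None
            if left.ref_id != right.ref_id:
                kind = "translocation"
            elif left.strand != right.strand:
                kind = "inversion"
            else:
                if left.strand == "+":
                    rgap = right.start - left.end
                    inverted = right.start < left.start
                else:
                    rgap = left.start - right.end
                    inverted = right.start > left.start
                if inverted or abs(rgap - qgap) > relocation_threshold:
                    kind = "relocation"
                elif rgap > 0:
                    captured.setdefault(left.ref_id, []).append(
                        (left.end, right.start)
                        if left.strand == "+"
                        else (right.end, left.start)
                    )
            if kind == "relocation":
                truth.n_relocations += 1
            elif kind == "inversion":
                truth.n_inversions += 1
            elif kind == "translocation":
                truth.n_translocations += 1
            if kind is not None:
                truth.misassembled_scaffolds.add(sid)

    for rid in ref:
        holes = subtract_intervals(
            [(0, len(ref[rid]))], merge_intervals(covered.get(rid, []))
        )
        if holes:
            truth.uncovered[rid] = holes
    truth.captured = {
        rid: merge_intervals(ivs) for rid, ivs in captured.items()
    }
    return assembly, truth


# ---------------------------------------------------------------------------
# Randomized fixtures with isolated edits
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    ref: ReferenceGenome
    regions: list[Region]
    assembly: AssemblySet
    truth: GroundTruth
    genome_plan: GenomePlan
    corruption: CorruptionPlan
    scaffold_cuts: list[int]


def random_fixture(
    seed: int,
    genome_length: int = 30_000,
    with_repeats: bool = True,
    relocation_threshold: int = 1000,
) -> Fixture:
    """Draw a random (genome, corruption) pair with isolated edits.

    Edits are kept far enough apart (and from scaffold cuts, repeat copies
    and each other) that an exact aligner must recover every planted event:
    point edits sit >= 100 bases from any block boundary, structural
    segments exceed the aligner's chain-gap limit so breakpoints cannot be
    absorbed as alignment gaps, and nothing overlaps a repeat copy.
    """
    rng = np.random.default_rng(seed)
    want_transloc = rng.random() < 0.3
    gplan = GenomePlan(
        length=genome_length,
        gc=0.43,
        repeat_blocks=[(600, 3, 0.02)] if with_repeats else [],
        gene_density=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
        extra_sequences=[8000] if want_transloc else [],
    )
    ref, regions = make_toy_genome(gplan)
    L = gplan.length

    # everything we must stay away from, with margins
    margin = 300
    occupied: list[Interval] = [
        (r.interval[0] - margin, r.interval[1] + margin)
        for r in regions
        if r.klass == "repeat"
    ]
    occupied += [(-1, margin), (L - margin, L + 1)]

    def claim(size: int) -> Interval:
        iv = _place(rng, occupied, size, L, margin=margin)
        occupied.append((iv[0] - margin, iv[1] + margin))
        return iv

    def claim_within(size: int, lo: int, hi: int, tries: int = 500) -> Interval | None:
        merged = merge_intervals(occupied)
        for _ in range(tries):
            if hi - lo <= size:
                return None
            start = int(rng.integers(lo, hi - size))
            iv = (start - margin, start + size + margin)
            if not any(s < iv[1] and iv[0] < e for s, e in merged):
                occupied.append(iv)
                return (start, start + size)
        return None

    # scaffold cuts (cut points get margins so edits stay clear of them)
    cuts: list[int] = []
    for _ in range(2):
        iv = claim(1)
        cuts.append(iv[0])
    cuts.sort()

    plan = CorruptionPlan(seed=int(rng.integers(0, 2**31 - 1)))

    if rng.random() < 0.4:  # dropped interval (uncaptured gap)
        size = int(rng.integers(500, 1500))
        iv = claim(size)
        plan.dropped_intervals.append(iv)

    # effective scaffold intervals after cuts and dropped-interval bounds
    scaffold_bounds = sorted(
        {0, L, *cuts, *(x for iv in plan.dropped_intervals for x in iv)}
    )
    scaffold_list = [
        (a, b)
        for a, b in zip(scaffold_bounds, scaffold_bounds[1:])
        if (a, b) not in plan.dropped_intervals
    ]

    if rng.random() < 0.5:  # relocation within the largest scaffold
        a, b = max(scaffold_list, key=lambda iv: iv[1] - iv[0])
        seg_len = int(rng.integers(2500, 4001))
        seg = claim_within(seg_len, a, b)
        if seg is not None:
            # insertion point >= 2500 from the segment so neither junction
            # can be absorbed by the aligner's gap closure
            merged_occ = merge_intervals(occupied)
            for _ in range(200):
                new_pos = int(rng.integers(a + margin, b - margin))
                if any(s <= new_pos < e for s, e in merged_occ):
                    continue
                if min(abs(new_pos - seg[0]), abs(new_pos - seg[1])) >= 2500:
                    plan.relocations.append((seg[0], seg[1], new_pos))
                    occupied.append((new_pos - margin, new_pos + margin))
                    break

    if rng.random() < 0.5:  # inversion
        size = int(rng.integers(300, 801))
        iv = claim(size)
        a, b = scaffold_of_iv(iv, scaffold_list)
        if iv[1] <= b:
            plan.inversions.append(iv)

    if want_transloc:  # splice a chr2 segment into chr1
        size = int(rng.integers(500, 1501))
        ins = claim(1)[0]
        chr1, chr2 = ref["chr1"], ref["chr2"]
        for _ in range(100):
            ds = int(rng.integers(100, 8000 - size - 100))
            # edge bases must differ from the insertion context, else an
            # exact-match aligner legitimately extends one base past the
            # planted junction and the coverage truth goes stale
            if chr2[ds - 1] != chr1[ins - 1] and chr2[ds + size] != chr1[ins]:
                plan.translocations.append(("chr2", ds, ds + size, ins))
                break

    for _ in range(int(rng.integers(0, 3))):  # captured gaps
        size = int(rng.integers(100, 201))
        iv = claim(size)
        plan.n_run_insertions.append(iv)

    for _ in range(int(rng.integers(0, 6))):  # substitutions
        iv = claim(1)
        plan.substitutions.append(iv[0])

    for _ in range(int(rng.integers(0, 4))):  # small indels
        size = int(rng.integers(1, 11))
        sign = 1 if rng.random() < 0.5 else -1
        iv = claim(max(1, size if sign < 0 else 1))
        plan.indels.append((iv[0], sign * size))

    assembly, truth = corrupt_assembly(
        ref, plan, cuts, relocation_threshold=relocation_threshold
    )
    return Fixture(ref, regions, assembly, truth, gplan, plan, cuts)


def scaffold_of_iv(
    iv: Interval, scaffold_list: list[Interval]
) -> Interval:
    for a, b in scaffold_list:
        if a <= iv[0] < b:
            return (a, b)
    raise ValueError(f"interval {iv} outside scaffolds")


def identity_assembly(
    ref: ReferenceGenome, n_scaffolds: int = 3, seq_id: str | None = None
) -> AssemblySet:
    """Partition a reference sequence into equal scaffolds, uncorrupted."""
    sid = seq_id or next(iter(ref))
    seq = ref[sid]
    L = len(seq)
    bounds = [round(i * L / n_scaffolds) for i in range(n_scaffolds + 1)]
    scaffolds = {
        f"scaffold_{i}": seq[a:b]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
    }
    return split_scaffolds(AssemblySet(scaffolds=scaffolds))
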