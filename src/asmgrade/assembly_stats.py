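"""Assembly summary statistics (contig and scaffold blocks).

The field set mirrors the flat per-run schema used throughout the package:
counts, total/average/largest lengths, N50, and the >1000 bp / >5000 bp
size-class counts (strict inequality, matching the printed '>' thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from .sequence_io import AssemblySet


@dataclass
class AssemblyStats:
    n_contigs: int
    total_contig_length: int
    average_contig_length: float
    contig_n50: int
    largest_contig_length: int
    contigs_gt_1000: int
    contigs_gt_5000: int
    n_scaffolds: int
    total_scaffold_length: int
    average_scaffold_length: float
    scaffold_n50: int
    largest_scaffold_length: int

    def as_dict(self) -> dict:
        return asdict(self)


def nxx(lengths: Sequence[int], fraction: float = 0.5) -> int:
    """Nxx statistic: sort descending, return the first length at which the
    cumulative sum reaches ``fraction`` of the total (the ">=" convention).

    N50 is ``nxx(lengths, 0.5)``.
    """
    if not lengths:
        raise ValueError("nxx of an empty length list")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ordered = sorted(lengths, reverse=True)
    threshold = fraction * sum(ordered)
    cum = 0
    for length in ordered:
        cum += length
        if cum >= threshold:
            return length
    return ordered[-1]  # unreachable: cum == total >= threshold


def _block(lengths: list[int]) -> tuple[int, int, float, int, int, int, int]:
    n = len(lengths)
    total = sum(lengths)
    return (
        n,
        total,
        round(total / n, 1),
        nxx(lengths, 0.5),
        max(lengths),
        sum(1 for x in lengths if x > 1000),
        sum(1 for x in lengths if x > 5000),
    )


def summarize_assembly(assembly: AssemblySet) -> AssemblyStats:
    """Compute the contig and scaffold statistics blocks.

    Scaffold lengths count N bases; contig lengths exclude split N runs but
    include any retained short runs. ``assembly.contigs`` must be populated
    (see :func:`asmgrade.sequence_io.split_scaffolds`).
    """
    if not assembly.scaffolds:
        raise ValueError("empty assembly")
    if not assembly.contigs:
        raise ValueError("assembly has no contigs; run split_scaffolds first")
    contig_lengths = [len(c) for c in assembly.contigs]
    scaffold_lengths = list(assembly.scaffold_lengths.values())
    nc, tc, ac, n50c, lc, gt1k, gt5k = _block(contig_lengths)
    ns, ts, as_, n50s, ls, _, _ = _block(scaffold_lengths)
    return AssemblyStats(
        n_contigs=nc,
        total_contig_length=tc,
        average_contig_length=ac,
        contig_n50=n50c,
        largest_contig_length=lc,
        contigs_gt_1000=gt1k,
        contigs_gt_5000=gt5k,
        n_scaffolds=ns,
        total_scaffold_length=ts,
        average_scaffold_length=as_,
        scaffold_n50=n50s,
        largest_scaffold_length=ls,
    )
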