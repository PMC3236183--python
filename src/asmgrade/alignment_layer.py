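"""Assembly-vs-reference alignment acquisition.

Three routes produce the same normalized :class:`AlignmentBlock` list:

* :func:`parse_coords` — MUMmer ``show-coords`` text (the aligner route the
  original nucmer-based pipeline used; invocation for users with MUMmer
  installed: ``nucmer -o -p <base name> <reference> <assembly>``);
* :func:`parse_paf` — minimap2-style PAF, optionally refined by a ``cg:Z``
  CIGAR tag;
* :func:`toy_align` — a built-in exact-anchor chainer so the whole pipeline
  runs self-contained at test scale without external binaries.

All blocks use 0-based half-open coordinates with query intervals on the
forward query strand; dialect quirks (1-based inclusive coords, reversed
query coordinates on minus-strand rows) are normalized at the parser
boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .sequence_io import AssemblySet, ReferenceGenome, reverse_complement

logger = logging.getLogger("asmgrade")

#: toy aligner defaults: anchor/k-mer size, max gap closed within one chain,
#: and the reference-size guard (it is a test-scale aligner, not nucmer).
DEFAULT_MIN_ANCHOR = 21
DEFAULT_CHAIN_GAP = 2000
TOY_ALIGN_MAX_REF = 10_000_000

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One contiguous assembly-to-reference alignment segment."""

    ref_id: str
    ref_start: int
    ref_end: int
    qry_id: str
    qry_start: int
    qry_end: int
    strand: str
    n_mismatch: int = 0
    n_indel_events: int = 0
    n_indel_bases: int = 0

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end and self.qry_start < self.qry_end):
            raise ValueError(
                f"degenerate block {self.ref_id}:{self.ref_start}-{self.ref_end}"
                f" / {self.qry_id}:{self.qry_start}-{self.qry_end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def aligned_ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def aligned_qry_len(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def columns(self) -> int:
        """Alignment columns: matches + mismatches + indel bases."""
        return (self.aligned_ref_len + self.aligned_qry_len + self.n_indel_bases) // 2

    @property
    def identity(self) -> float:
        cols = self.columns
        return (cols - self.n_mismatch - self.n_indel_bases) / cols

    @property
    def score(self) -> float:
        """Chain/tiling score: identity x aligned query length."""
        return self.identity * self.aligned_qry_len


def _counts_from_cigar(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, indel events, indel bases) from an =/X CIGAR.

    Plain ``M`` ops are counted as matches (no way to tell), which matches
    how PAF column 10 is then reconciled by the caller.
    """
    m = x = events = bases = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "=M":
            m += n
        elif op == "X":
            x += n
        else:  # I or D
            events += 1
            bases += n
    return m, x, events, bases


# ---------------------------------------------------------------------------
# MUMmer show-coords dialect
# ---------------------------------------------------------------------------

def _coords_row(tokens: list[str], line_no: int, path: str) -> AlignmentBlock:
    try:
        s1, e1, s2, e2 = (int(t) for t in tokens[:4])
        len1, len2 = int(tokens[4]), int(tokens[5])
        idy = float(tokens[6])
        ref_id, qry_id = tokens[7], tokens[8]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{line_no}: malformed show-coords row") from exc
    # reference is always forward in show-coords; 1-based inclusive
    ref_start, ref_end = s1 - 1, e1
    if s2 <= e2:
        strand, qry_start, qry_end = "+", s2 - 1, e2
    else:
        strand, qry_start, qry_end = "-", e2 - 1, s2
    # per-event counts are absent from show-coords: reconstruct total error
    # bases from identity x columns; the length difference is the indel
    # floor and the remainder is taken as mismatches (documented
    # approximation; each reconstructed indel base counts as one event)
    indel_bases = abs(len1 - len2)
    columns = (len1 + len2 + indel_bases) // 2
    errors = round((1.0 - idy / 100.0) * columns)
    n_mismatch = max(errors - indel_bases, 0)
    return AlignmentBlock(
        ref_id=ref_id,
        ref_start=ref_start,
        ref_end=ref_end,
        qry_id=qry_id,
        qry_start=qry_start,
        qry_end=qry_end,
        strand=strand,
        n_mismatch=n_mismatch,
        n_indel_events=indel_bases,
        n_indel_bases=indel_bases,
    )


def parse_coords(path: str | Path) -> list[AlignmentBlock]:
    """Parse MUMmer ``show-coords`` output (default or ``-T`` tab layout).

    Header material (file paths, ``NUCMER``, column captions, rules) is
    skipped; a header-only file yields an empty list. Data rows must carry
    the identity column (``show-coords`` default)."""
    blocks: list[AlignmentBlock] = []
    path = str(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            tokens = [t for t in line.replace("|", " ").split() if t]
            if not tokens:
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # header / caption line
            if len(tokens) == 1 and set(line) <= set("=- \n"):
                continue
            blocks.append(_coords_row(tokens, ln, path))
    return blocks


def write_coords(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Write blocks in show-coords tab layout (fixture/round-trip writer)."""
    with open(path, "w") as fh:
        fh.write("asmgrade coords\nNUCMER\n\n")
        fh.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n")
        for b in blocks:
            s1, e1 = b.ref_start + 1, b.ref_end
            if b.strand == "+":
                s2, e2 = b.qry_start + 1, b.qry_end
            else:
                s2, e2 = b.qry_end, b.qry_start + 1
            fh.write(
                f"{s1}\t{e1}\t{s2}\t{e2}\t{b.aligned_ref_len}\t"
                f"{b.aligned_qry_len}\t{100.0 * b.identity:.6f}\t"
                f"{b.ref_id}\t{b.qry_id}\n"
            )


# ---------------------------------------------------------------------------
# PAF dialect
# ---------------------------------------------------------------------------

def parse_paf(path: str | Path) -> list[AlignmentBlock]:
    """Parse 12+-column PAF. Coordinates are already 0-based half-open with
    forward-strand query intervals. Without a ``cg:Z`` tag, the length
    difference is the indel floor and the remaining error bases
    (block length - matches) are mismatches; a CIGAR refines event counts."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{ln}: PAF needs >= 12 columns")
            qry_id = cols[0]
            qry_start, qry_end = int(cols[2]), int(cols[3])
            strand = cols[4]
            ref_id = cols[5]
            ref_start, ref_end = int(cols[7]), int(cols[8])
            matches, block_len = int(cols[9]), int(cols[10])
            cigar = None
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            if cigar is not None:
                cig_m, n_mismatch, events, indel_bases = _counts_from_cigar(cigar)
                if cig_m not in (matches, matches + n_mismatch):
                    # with an =/X CIGAR the '=' count should equal column 10
                    logger.warning(
                        "%s:%d: CIGAR and matches column disagree", path, ln
                    )
            else:
                indel_bases = abs(
                    (qry_end - qry_start) - (ref_end - ref_start)
                )
                n_mismatch = max(block_len - matches - indel_bases, 0)
                events = indel_bases
            blocks.append(
                AlignmentBlock(
                    ref_id=ref_id,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    qry_id=qry_id,
                    qry_start=qry_start,
                    qry_end=qry_end,
                    strand=strand,
                    n_mismatch=n_mismatch,
                    n_indel_events=events,
                    n_indel_bases=indel_bases,
                )
            )
    return blocks


def write_paf(
    blocks: Iterable[AlignmentBlock],
    path: str | Path,
    qry_lengths: Mapping[str, int] | None = None,
    ref_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write blocks as 12-column PAF (fixture/round-trip writer)."""
    qry_lengths = qry_lengths or {}
    ref_lengths = ref_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            cols = b.columns
            matches = cols - b.n_mismatch - b.n_indel_bases
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.qry_id,
                        qry_lengths.get(b.qry_id, b.qry_end),
                        b.qry_start,
                        b.qry_end,
                        b.strand,
                        b.ref_id,
                        ref_lengths.get(b.ref_id, b.ref_end),
                        b.ref_start,
                        b.ref_end,
                        matches,
                        cols,
                        255,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Toy aligner: exact k-mer anchors -> greedy diagonal chains -> edlib-closed
# gaps
# ---------------------------------------------------------------------------

def _kmer_index(ref: ReferenceGenome, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for rid in ref:
        seq = ref[rid]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((rid, i))
    return index


def _anchors(
    qseq: str,
    index: Mapping[str, list[tuple[str, int]]],
    k: int,
    min_anchor: int,
) -> dict[str, list[tuple[int, int, int, int]]]:
    """Maximal exact matches >= min_anchor, per reference id.

    Returns rid -> list of (qry_start, qry_end, ref_start, ref_end), where
    consecutive k-mer hits on one diagonal are merged into one anchor.
    """
    by_diag: dict[tuple[str, int], list[int]] = {}
    for i in range(len(qseq) - k + 1):
        kmer = qseq[i : i + k]
        if "N" in kmer:
            continue
        for rid, rpos in index.get(kmer, ()):
            by_diag.setdefault((rid, rpos - i), []).append(i)
    out: dict[str, list[tuple[int, int, int, int]]] = {}
    for (rid, diag), positions in by_diag.items():
        positions.sort()
        run_start = prev = positions[0]
        for pos in positions[1:] + [None]:  # type: ignore[list-item]
            if pos is not None and pos == prev + 1:
                prev = pos
                continue
            qs, qe = run_start, prev + k
            if qe - qs >= min_anchor:
                out.setdefault(rid, []).append((qs, qe, qs + diag, qe + diag))
            if pos is not None:
                run_start = prev = pos
    for rid in out:
        out[rid].sort()
    return out


def _close_gap(qgap: str, rgap: str) -> tuple[int, int, int, int] | None:
    """Align the inter-anchor gap end-to-end with unit costs.

    Returns (matches, mismatches, indel events, indel bases), or None when
    the gap is not alignable — edit distance above 0.3 x the gap length for
    gaps longer than 20 bases (unrelated DNA sits near 0.47, homologous
    sequence far below) — e.g. a short inverted segment between collinear
    flanks, in which case the chain must split there."""
    if not qgap and not rgap:
        return 0, 0, 0, 0
    longest = max(len(qgap), len(rgap))
    if not qgap or not rgap:
        if longest > 20:
            return None
        return 0, 0, 1, len(qgap) + len(rgap)
    res = edlib.align(qgap, rgap, task="path", mode="NW")
    if longest > 20 and res["editDistance"] > 0.3 * longest:
        return None
    return _counts_from_cigar(res["cigar"])


def _chain_anchors(
    anchors: list[tuple[int, int, int, int]],
    qseq: str,
    chain_gap: int,
) -> list[list[tuple[int, int, int, int]]]:
    """Greedy collinear chaining in query order.

    An anchor extends a chain when it progresses on both query and
    reference, both gaps are <= chain_gap, and the query gap contains no N
    (so chains never bridge scaffold N runs; those holes surface as
    captured gaps downstream). Among compatible chains the one with the
    smallest combined gap wins, so chains do not hop between near-identical
    repeat copies. Small overlaps from adjacent diagonals are trimmed off
    the incoming anchor."""
    chains: list[list[tuple[int, int, int, int]]] = []
    for anchor in anchors:
        qs, qe, rs, re_ = anchor
        best: tuple[int, int] | None = None  # (combined gap, chain index)
        best_anchor = anchor
        for idx, chain in enumerate(chains):
            pqs, pqe, prs, pre = chain[-1]
            aqs, aqe, ars, are = qs, qe, rs, re_
            # overlaps between anchors on adjacent diagonals are a few
            # bases (around indels); a large overlap means the chain is
            # trying to swallow an anchor that belongs elsewhere
            trim_cap = 50
            if aqs < pqe:  # trim query overlap along the diagonal
                delta = pqe - aqs
                if delta > trim_cap:
                    continue
                aqs += delta
                ars += delta
            if ars < pre:  # trim residual reference overlap
                delta = pre - ars
                if delta > trim_cap:
                    continue
                ars += delta
                aqs += delta
            if aqe - aqs < 1 or aqe <= pqe or are <= pre:
                continue
            qgap = aqs - pqe
            rgap = ars - pre
            if qgap > chain_gap or rgap > chain_gap:
                continue
            if "N" in qseq[pqe:aqs]:
                continue
            combined = qgap + rgap
            if best is None or combined < best[0]:
                best = (combined, idx)
                best_anchor = (aqs, aqe, ars, are)
        if best is not None:
            chains[best[1]].append(best_anchor)
        else:
            chains.append([anchor])
    return chains


def toy_align(
    ref: ReferenceGenome,
    assembly: AssemblySet,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    chain_gap: int = DEFAULT_CHAIN_GAP,
    max_ref: int = TOY_ALIGN_MAX_REF,
) -> list[AlignmentBlock]:
    """Self-contained exact-anchor aligner for test-scale genomes.

    For every scaffold and both strands: maximal exact matches >= min_anchor
    found through a reference k-mer index are chained greedily along
    diagonals, and the gaps between chained anchors are closed with
    end-gap-free global alignment at unit costs, giving exact mismatch and
    indel counts per block. Chains anchored by fewer than ``min_anchor``
    matching bases are dropped. Deterministic; ties between equal-score
    chains resolve to (lower ref_start, then + strand) via the output sort.
    """
    if ref.total_length > max_ref:
        raise ValueError(
            f"reference is {ref.total_length} bp > toy aligner guard "
            f"{max_ref}; align externally (e.g. nucmer/minimap2) and use "
            "parse_coords/parse_paf"
        )
    k = min(21, min_anchor)
    index = _kmer_index(ref, k)
    blocks: list[AlignmentBlock] = []
    for qid, scaffold in assembly.scaffolds.items():
        qlen = len(scaffold)
        for strand in "+-":
            qseq = scaffold if strand == "+" else reverse_complement(scaffold)
            per_ref = _anchors(qseq, index, k, min_anchor)
            for rid, anchor_list in sorted(per_ref.items()):
                rseq = ref[rid]
                for chain in _chain_anchors(anchor_list, qseq, chain_gap):
                    # split the chain wherever a gap is not alignable
                    runs: list[tuple[list, list[int]]] = [([chain[0]], [0, 0, 0, 0])]
                    for prev, nxt in zip(chain, chain[1:]):
                        closed = _close_gap(
                            qseq[prev[1] : nxt[0]], rseq[prev[3] : nxt[2]]
                        )
                        if closed is None:
                            runs.append(([nxt], [0, 0, 0, 0]))
                        else:
                            counts = runs[-1][1]
                            for i in range(4):
                                counts[i] += closed[i]
                            runs[-1][0].append(nxt)
                    for run, (_, mism, events, ibases) in runs:
                        anchored = sum(qe - qs for qs, qe, _, _ in run)
                        if anchored < min_anchor:
                            continue
                        q0, q1 = run[0][0], run[-1][1]
                        r0, r1 = run[0][2], run[-1][3]
                        if strand == "+":
                            f0, f1 = q0, q1
                        else:
                            f0, f1 = qlen - q1, qlen - q0
                        blocks.append(
                            AlignmentBlock(
                                ref_id=rid,
                                ref_start=r0,
                                ref_end=r1,
                                qry_id=qid,
                                qry_start=f0,
                                qry_end=f1,
                                strand=strand,
                                n_mismatch=mism,
                                n_indel_events=events,
                                n_indel_bases=ibases,
                            )
                        )
    # subsumed duplicate chains (a repeat copy aligning inside a larger
    # chain's span with identical coordinates) cannot arise: chains are
    # keyed by distinct anchor sets; just order deterministically
    blocks.sort(
        key=lambda b: (b.qry_id, b.qry_start, b.ref_id, b.ref_start, b.strand)
    )
    return blocks


def load_alignments(path: str | Path) -> list[AlignmentBlock]:
    """Dispatch on file extension: ``.paf`` -> PAF, else show-coords."""
    if str(path).endswith(".paf"):
        return parse_paf(path)
    return parse_coords(path)
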