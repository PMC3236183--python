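"""Sequence and annotation I/O.

FASTA references and assemblies, GFF3 region annotations, and the
scaffold-to-contig split at long runs of ambiguous bases.

Coordinate conventions
----------------------
Everything internal is 0-based half-open. The two external formats that use
1-based inclusive coordinates (GFF3 and MUMmer ``show-coords``) are converted
at their parser/writer boundaries and nowhere else. :class:`Region` keeps the
GFF's own 1-based inclusive ``start``/``end`` fields verbatim and exposes the
internal convention through :attr:`Region.interval`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("asmgrade")

#: Default minimum N-run length at which a scaffold is split into contigs.
DEFAULT_MIN_N_RUN = 10

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Protein-family keyword table used to assign a family class to CDS rows by
#: substring match against the product/Note/description attribute. The keys
#: are matched case-insensitively; unmatched rows get class "other".
PROTEIN_FAMILY_KEYWORDS: dict[str, str] = {
    "protein kinase": "protein kinase",
    "zn-finger": "Zn-finger",
    "zinc finger": "Zn-finger",
    "bhlh": "bHLH",
    "helix-loop-helix": "bHLH",
    "mads": "MADS",
    "abc transporter": "ABC transporter",
    "f-box": "F-box",
    "cytochrome p450": "Cytochrome P450",
    "ap2": "AP2",
    "myb": "MYB",
    "udp-gluc": "UDP-gluc",
    "tpr": "TPR",
    "tetratricopeptide": "TPR",
    "hmg": "HMG",
    "phosphatase": "phosphatase",
    "rna binding": "RNA binding",
    "rna-binding": "RNA binding",
    "glycoside hydrolase": "Glycoside hydrolase",
    "leucine-rich repeat": "Leucine-rich repeat",
}


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and collapse every non-ACGT residue to ``N``.

    Returns the normalized string and the number of residues (excluding
    literal ``n``/``N``) that were mapped to ``N``.
    """
    up = seq.upper()
    if set(up) <= _VALID:
        return up, 0
    mapped = 0
    out = []
    for ch in up:
        if ch in _VALID:
            out.append(ch)
        else:
            out.append("N")
            mapped += 1
    return "".join(out), mapped


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Named nucleotide sequences; the coordinate authority for all metrics.

    ``sequences`` maps sequence id to an uppercase string over {A,C,G,T,N};
    insertion order is preserved and ids are unique.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not sid:
                raise ValueError("empty sequence id")
            if len(seq) < 1:
                raise ValueError(f"sequence {sid!r} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences


@dataclass
class Contig:
    """A gap-free stretch of a scaffold (may retain short N runs)."""

    scaffold_id: str
    offset: int  # 0-based start within the scaffold
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}.{self.offset}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblySet:
    """Assembly scaffolds plus the contigs derived by splitting at N runs."""

    scaffolds: dict[str, str]
    contigs: list[Contig] = field(default_factory=list)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.scaffolds.items()}

    @property
    def ambiguous_bases(self) -> int:
        """Total N characters in the scaffold consensus."""
        return sum(s.count("N") for s in self.scaffolds.values())


@dataclass
class Region:
    """One annotated interval, in the GFF's 1-based inclusive coordinates."""

    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    klass: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region coordinates {self.start}..{self.end}")
        if not self.klass:
            raise ValueError("empty region class")

    @property
    def interval(self) -> tuple[int, int]:
        """The region as a 0-based half-open (start, end) pair."""
        return self.start - 1, self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _read_fasta_records(path: str | Path) -> dict[str, str]:
    path = Path(path)
    sequences: dict[str, str] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in sequences:
            raise ValueError(f"duplicate sequence id {sid!r} in {path}")
        seq, mapped = normalize_sequence(str(rec.seq))
        n_mapped += mapped
        sequences[sid] = seq
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    if n_mapped:
        logger.warning(
            "%s: %d non-ACGTN residues mapped to N", path.name, n_mapped
        )
    return sequences


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (multi-)FASTA file as a reference genome.

    Ids are the first whitespace-delimited token of each header; sequences
    are uppercased with IUPAC ambiguity codes collapsed to N (warned, not
    rejected, so real references parse). Duplicate ids are a hard error.
    """
    return ReferenceGenome(_read_fasta_records(path))


def read_assembly(path: str | Path, min_n_run: int = DEFAULT_MIN_N_RUN) -> AssemblySet:
    """Read assembly scaffolds and split them into contigs."""
    asm = AssemblySet(scaffolds=_read_fasta_records(path))
    return split_scaffolds(asm, min_n_run)


def write_fasta(
    sequences: Mapping[str, str], path: str | Path, width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Scaffold -> contig split
# ---------------------------------------------------------------------------

def n_runs(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of N of length >= ``min_len`` as 0-based half-open pairs."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def split_scaffolds(
    assembly: AssemblySet, min_n_run: int = DEFAULT_MIN_N_RUN
) -> AssemblySet:
    """Split every scaffold into contigs at maximal N runs >= ``min_n_run``.

    Shorter N runs stay inside contigs; all-N leading/trailing stretches
    produce no empty contigs. Concatenating a scaffold's contigs with its
    split N runs reconstructs the scaffold exactly.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    contigs: list[Contig] = []
    for sid, seq in assembly.scaffolds.items():
        pos = 0
        for start, end in n_runs(seq, min_n_run):
            if start > pos:
                contigs.append(Contig(sid, pos, seq[pos:start]))
            pos = end
        if pos < len(seq):
            contigs.append(Contig(sid, pos, seq[pos:]))
    return AssemblySet(scaffolds=assembly.scaffolds, contigs=contigs)


# ---------------------------------------------------------------------------
# GFF3 regions
# ---------------------------------------------------------------------------

def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def classify_product(
    text: str, keywords: Mapping[str, str] = PROTEIN_FAMILY_KEYWORDS
) -> str:
    """Assign a protein-family class by substring match against ``text``."""
    low = text.lower()
    for needle, klass in keywords.items():
        if needle in low:
            return klass
    return "other"


def read_gff_regions(
    path: str | Path,
    feature_filter: set[str],
    klass_from: str = "type",
    keywords: Mapping[str, str] = PROTEIN_FAMILY_KEYWORDS,
) -> list[Region]:
    """Read GFF3 rows whose feature type is in ``feature_filter`` as Regions.

    ``klass_from`` is either ``"type"`` (class = GFF column 3) or the name of
    a column-9 attribute (e.g. ``product`` or ``Note``) whose value is matched
    against the protein-family keyword table to assign a family class.
    Overlapping rows are all kept; merging happens downstream where a class's
    intervals form a coverage denominator. Rows with start > end are skipped
    with a warning.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF columns")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols[:9]
            if ftype not in feature_filter:
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                logger.warning("%s:%d: start > end, row skipped", path, ln)
                continue
            if klass_from == "type":
                klass = ftype
            else:
                attrs = _parse_attributes(attrs_s)
                klass = classify_product(attrs.get(klass_from, ""), keywords)
            regions.append(Region(seq_id, start, end, klass, strand))
    return regions


def write_gff_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as minimal GFF3 (class in column 3 and as an attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(regions, 1):
            fh.write(
                f"{r.seq_id}\tasmgrade\t{r.klass}\t{r.start}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID=region{i};klass={r.klass}\n"
            )


def check_regions(regions: Sequence[Region], ref: ReferenceGenome) -> None:
    """Validate regions against the reference (hard error on unknown ids)."""
    lengths = ref.lengths
    for r in regions:
        if r.seq_id not in lengths:
            raise ValueError(f"region sequence id {r.seq_id!r} absent from reference")
        if r.end > lengths[r.seq_id]:
            raise ValueError(
                f"region {r.seq_id}:{r.start}-{r.end} exceeds reference length "
                f"{lengths[r.seq_id]}"
            )
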