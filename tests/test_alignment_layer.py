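"""Alignment acquisition: coords/PAF dialects and the toy aligner."""

import pytest

from asmgrade import (
    AssemblySet,
    GenomePlan,
    make_toy_genome,
    parse_coords,
    parse_paf,
    split_scaffolds,
    toy_align,
    write_coords,
    write_paf,
)
from asmgrade.alignment_layer import AlignmentBlock, _counts_from_cigar
from asmgrade.sequence_io import ReferenceGenome, reverse_complement

COORDS = """ref.fasta qry.fasta
NUCMER

    [S1]  [E1] | [S2]  [E2] | [LEN 1] [LEN 2] | [% IDY] | [TAGS]
       1   100 |    1   100 |     100     100 |  100.00 | chr1 ctg1
     201   300 |  200   101 |     100     100 |   98.00 | chr1 ctg2
"""


class TestParseCoords:
    def test_forward_row_normalized(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(COORDS)
        blocks = parse_coords(p)
        b = blocks[0]
        assert (b.ref_start, b.ref_end) == (0, 100)
        assert (b.qry_start, b.qry_end) == (0, 100)
        assert b.strand == "+"
        assert b.identity == 1.0

    def test_reversed_query_coordinates_mean_minus_strand(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(COORDS)
        b = parse_coords(p)[1]
        assert b.strand == "-"
        assert (b.qry_start, b.qry_end) == (100, 200)
        assert b.n_mismatch == 2  # reconstructed from 98% identity

    def test_header_only_file_is_empty_not_error(self, tmp_path):
        p = tmp_path / "h.coords"
        p.write_text("ref qry\nNUCMER\n\n[S1] [E1]\n")
        assert parse_coords(p) == []

    def test_malformed_row_is_hard_error_with_line(self, tmp_path):
        p = tmp_path / "bad.coords"
        p.write_text("1 2 three 4 5 6 7 chr1 ctg1\n")
        with pytest.raises(ValueError, match="bad.coords:1"):
            parse_coords(p)

    def test_parse_write_parse_identity(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(COORDS)
        first = parse_coords(p)
        q = tmp_path / "b.coords"
        write_coords(first, q)
        assert parse_coords(q) == first


class TestParsePaf:
    def _paf(self, tmp_path, body):
        p = tmp_path / "a.paf"
        p.write_text(body)
        return p

    def test_perfect_block(self, tmp_path):
        p = self._paf(
            tmp_path, "ctg1\t100\t0\t100\t+\tchr1\t1000\t0\t100\t100\t100\t60\n"
        )
        (b,) = parse_paf(p)
        assert b.identity == 1.0
        assert (b.ref_start, b.ref_end) == (0, 100)

    def test_error_bases_without_cigar(self, tmp_path):
        p = self._paf(
            tmp_path, "ctg1\t100\t0\t100\t+\tchr1\t1000\t0\t100\t95\t100\t60\n"
        )
        (b,) = parse_paf(p)
        assert b.n_mismatch + b.n_indel_bases == 5

    def test_cigar_refines_counts(self, tmp_path):
        p = self._paf(
            tmp_path,
            "ctg1\t100\t0\t100\t+\tchr1\t1000\t0\t100\t99\t100\t60\tcg:Z:50=1X49=\n",
        )
        (b,) = parse_paf(p)
        assert b.n_mismatch == 1
        assert b.n_indel_events == 0

    def test_short_line_rejected(self, tmp_path):
        p = self._paf(tmp_path, "ctg1\t100\t0\t100\t+\tchr1\t1000\t0\t100\t95\n")
        with pytest.raises(ValueError, match="12 columns"):
            parse_paf(p)

    def test_parse_write_parse_identity(self, tmp_path):
        p = self._paf(
            tmp_path,
            "ctg1\t100\t0\t100\t+\tchr1\t1000\t0\t100\t95\t100\t60\n"
            "ctg2\t300\t10\t210\t-\tchr1\t1000\t400\t600\t198\t200\t60\n",
        )
        first = parse_paf(p)
        q = tmp_path / "b.paf"
        write_paf(first, q)
        assert parse_paf(q) == first


def test_cigar_walk_counts():
    assert _counts_from_cigar("50=1X49=") == (99, 1, 0, 0)
    assert _counts_from_cigar("10=2I5=1D10=") == (25, 0, 2, 3)


class TestBlockInvariants:
    def test_identity_definition(self):
        b = AlignmentBlock("r", 0, 100, "q", 0, 98, "+", n_mismatch=3,
                           n_indel_events=1, n_indel_bases=2)
        # columns = (100 + 98 + 2)/2 = 100
        assert b.columns == 100
        assert b.identity == (100 - 3 - 2) / 100
        assert abs(b.aligned_ref_len - b.aligned_qry_len) <= b.n_indel_bases

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            AlignmentBlock("r", 10, 10, "q", 0, 5, "+")


@pytest.fixture(scope="module")
def genome():
    return make_toy_genome(GenomePlan(length=20_000, seed=11))[0]


class TestToyAlign:

    def _asm(self, **scaffolds):
        return split_scaffolds(AssemblySet(scaffolds=scaffolds))

    def test_exact_substring_single_perfect_block(self, genome):
        asm = self._asm(q=genome["chr1"][5000:6000])
        (b,) = toy_align(genome, asm)
        assert (b.ref_start, b.ref_end, b.strand) == (5000, 6000, "+")
        assert b.identity == 1.0
        assert (b.qry_start, b.qry_end) == (0, 1000)

    def test_reverse_complement_minus_strand(self, genome):
        asm = self._asm(q=reverse_complement(genome["chr1"][8000:9000]))
        (b,) = toy_align(genome, asm)
        assert (b.ref_start, b.ref_end, b.strand) == (8000, 9000, "-")
        assert b.identity == 1.0

    def test_planted_substitution_counted_once(self, genome):
        s = list(genome["chr1"][12_000:13_000])
        s[500] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[500]]
        (b,) = toy_align(genome, self._asm(q="".join(s)))
        assert b.n_mismatch == 1
        assert b.n_indel_events == 0
        assert b.identity == pytest.approx(999 / 1000)

    def test_planted_insertion_one_event(self, genome):
        seg = genome["chr1"][3000:4000]
        q = seg[:500] + "ACGTA" + seg[500:]
        (b,) = toy_align(genome, self._asm(q=q))
        assert b.n_indel_events == 1
        assert b.n_indel_bases == 5
        assert b.n_mismatch == 0

    def test_uncorrupted_partition_covers_contigs_perfectly(self, genome):
        third = genome.total_length // 3
        asm = self._asm(
            a=genome["chr1"][:third],
            b=genome["chr1"][third : 2 * third],
            c=genome["chr1"][2 * third :],
        )
        blocks = toy_align(genome, asm)
        assert len(blocks) == 3
        assert all(b.identity == 1.0 for b in blocks)
        covered = sorted((b.ref_start, b.ref_end) for b in blocks)
        assert covered == [(0, third), (third, 2 * third), (2 * third, 20_000)]

    def test_chain_refuses_to_bridge_n_runs(self, genome):
        q = genome["chr1"][1000:2000] + "N" * 120 + genome["chr1"][2120:3000]
        blocks = toy_align(genome, self._asm(q=q))
        assert len(blocks) == 2
        assert {(b.ref_start, b.ref_end) for b in blocks} == {
            (1000, 2000),
            (2120, 3000),
        }

    def test_reference_size_guard(self):
        ref = ReferenceGenome({"r": "ACGT" * 30})
        asm = self._asm(q="ACGT" * 10)
        with pytest.raises(ValueError, match="guard"):
            toy_align(ref, asm, max_ref=100)
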