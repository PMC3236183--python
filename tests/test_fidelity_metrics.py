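"""Fidelity engine: classification, representation, rates, gap accounting."""

import pytest

from asmgrade import (
    AssemblySet,
    FidelityConfig,
    GenomePlan,
    classify_query,
    compute_error_rates,
    compute_gaps,
    compute_representation,
    evaluate,
    identity_assembly,
    make_toy_genome,
    split_scaffolds,
    toy_align,
)
from asmgrade.alignment_layer import AlignmentBlock
from asmgrade.fidelity_metrics import (
    genome_map,
    interval_total,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)
from asmgrade.sequence_io import ReferenceGenome


def block(ref_start, ref_end, qry_start, qry_end, strand="+", qry="q",
          ref="chr1", mism=0, iev=0, ib=0):
    return AlignmentBlock(ref, ref_start, ref_end, qry, qry_start, qry_end,
                          strand, n_mismatch=mism, n_indel_events=iev,
                          n_indel_bases=ib)


class TestIntervalOps:
    def test_merge_union_subtract(self):
        assert merge_intervals([(0, 50), (40, 80)]) == [(0, 80)]
        assert intersect_intervals([(0, 80)], [(30, 100)]) == [(30, 80)]
        assert subtract_intervals([(0, 100)], [(0, 40), (60, 100)]) == [(40, 60)]
        assert interval_total([(0, 10), (20, 25)]) == 15


class TestClassifyQuery:
    def test_single_full_block_aligned(self):
        v = classify_query([block(0, 1000, 0, 1000)], 1000)
        assert v.status == "ALIGNED"
        assert v.breakpoints == []
        assert v.unaligned_bases == 0

    def test_no_blocks_unaligned(self):
        v = classify_query([], 500)
        assert v.status == "UNALIGNED"
        assert v.kept_blocks == []
        assert v.unaligned_bases == 500

    def test_distant_halves_are_a_relocation(self):
        v = classify_query(
            [block(0, 500, 0, 500), block(10_500, 11_000, 500, 1000)], 1000
        )
        assert v.status == "MISASSEMBLED"
        assert [bp.kind for bp in v.breakpoints] == ["relocation"]

    def test_small_jump_not_flagged(self):
        v = classify_query(
            [block(0, 500, 0, 500), block(900, 1400, 500, 1000)], 1000
        )
        assert v.status == "ALIGNED"

    def test_strand_flip_is_inversion(self):
        v = classify_query(
            [block(0, 500, 0, 500), block(500, 1000, 500, 1000, strand="-")],
            1000,
        )
        assert [bp.kind for bp in v.breakpoints] == ["inversion"]

    def test_reference_change_is_translocation(self):
        v = classify_query(
            [block(0, 500, 0, 500), block(0, 500, 500, 1000, ref="chr2")], 1000
        )
        assert [bp.kind for bp in v.breakpoints] == ["translocation"]

    def test_two_repeat_copies_whole_query_ambiguous(self):
        a = block(1000, 2000, 0, 1000, mism=5)
        b = block(8000, 9000, 0, 1000, mism=6)
        v = classify_query([a, b], 1000)
        assert v.status == "AMBIGUOUS"
        assert v.contested_bases == 1000
        assert v.kept_blocks  # best tiling still recorded

    def test_clear_identity_gap_not_ambiguous(self):
        a = block(1000, 2000, 0, 1000)
        b = block(8000, 9000, 0, 1000, mism=50)
        v = classify_query([a, b], 1000)
        assert v.status == "ALIGNED"
        assert v.kept_blocks == [a]

    def test_partial_when_tail_unaligned(self):
        v = classify_query([block(0, 800, 0, 800)], 1000)
        assert v.status == "PARTIAL"
        assert v.unaligned_bases == 200

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            classify_query(
                [block(0, 100, 0, 100, qry="a"), block(0, 100, 0, 100, qry="b")],
                100,
            )


class TestRepresentation:
    def test_interval_union_arithmetic(self):
        rep, covered = compute_representation(
            [block(0, 50, 0, 50), block(40, 80, 50, 90)],
            {"chr1": [(0, 100)]},
        )
        assert rep == pytest.approx(0.80)
        assert covered == {"chr1": [(0, 80)]}

    def test_no_blocks_zero(self):
        rep, covered = compute_representation([], {"chr1": [(0, 100)]})
        assert rep == 0.0

    def test_exact_tiling_is_one(self):
        rep, _ = compute_representation(
            [block(0, 60, 0, 60), block(60, 100, 0, 40, qry="q2")],
            {"chr1": [(0, 100)]},
        )
        assert rep == 1.0

    def test_monotone_under_block_removal(self):
        blocks = [block(0, 50, 0, 50), block(30, 90, 0, 60, qry="q2")]
        region = {"chr1": [(0, 100)]}
        full = compute_representation(blocks, region)[0]
        for i in range(len(blocks)):
            less = compute_representation(blocks[:i] + blocks[i + 1 :], region)[0]
            assert less <= full


class TestErrorRates:
    def test_per_100kb_scaling(self):
        blocks = [block(0, 100_000, 0, 100_000, mism=5, iev=2, ib=2)]
        mm, ind, err, aligned = compute_error_rates(blocks, {"chr1": [(0, 100_000)]})
        assert (mm, ind, err) == (5.0, 2.0, 7.0)
        assert aligned == 100_000

    def test_perfect_blocks_zero(self):
        blocks = [block(0, 1000, 0, 1000)]
        assert compute_error_rates(blocks, {"chr1": [(0, 1000)]})[:3] == (0, 0, 0)

    def test_proportional_apportionment(self):
        # block half inside the region, 10 mismatches -> 5 attributed
        blocks = [block(0, 1000, 0, 1000, mism=10)]
        mm, _, _, aligned = compute_error_rates(
            blocks, {"chr1": [(500, 1000)]}, rate_scale=1.0
        )
        assert aligned == 500
        assert mm * aligned == pytest.approx(5.0)

    def test_error_rate_is_exact_sum(self):
        blocks = [block(0, 997, 0, 1000, mism=7, iev=3, ib=3)]
        mm, ind, err, _ = compute_error_rates(blocks, {"chr1": [(0, 2000)]})
        assert err == mm + ind


class TestGaps:
    def test_captured_gap_within_one_scaffold(self):
        blocks = [block(0, 40, 0, 40), block(60, 100, 60, 100)]
        v = classify_query(blocks, 100, FidelityConfig(min_block_length=10))
        gaps = compute_gaps([v], blocks, {"chr1": [(0, 100)]})
        assert gaps.n_gaps == 1
        assert gaps.total_gap_bases == 20
        assert gaps.n_captured_gaps == 1
        assert gaps.total_captured_gap_bases == 20

    def test_negative_gap_between_consecutive_blocks(self):
        blocks = [block(0, 50, 0, 50), block(44, 100, 50, 106)]
        v = classify_query(blocks, 106, FidelityConfig(min_block_length=10))
        gaps = compute_gaps([v], blocks, {"chr1": [(0, 100)]})
        assert gaps.n_negative_gaps == 1
        assert gaps.avg_negative_gap_size == 6

    def test_full_coverage_no_gaps(self):
        blocks = [block(0, 100, 0, 100)]
        v = classify_query(blocks, 100, FidelityConfig(min_block_length=10))
        gaps = compute_gaps([v], blocks, {"chr1": [(0, 100)]})
        assert (gaps.n_gaps, gaps.n_captured_gaps, gaps.total_gap_bases) == (0, 0, 0)

    def test_gap_flanked_by_different_scaffolds_not_captured(self):
        blocks = [block(0, 40, 0, 40, qry="a"), block(60, 100, 0, 40, qry="b")]
        va = classify_query([blocks[0]], 40)
        vb = classify_query([blocks[1]], 40)
        gaps = compute_gaps([va, vb], blocks, {"chr1": [(0, 100)]})
        assert gaps.n_gaps == 1
        assert gaps.n_captured_gaps == 0


@pytest.fixture(scope="module")
def genome():
    return make_toy_genome(
        GenomePlan(length=40_000, repeat_blocks=[(600, 3, 0.02)], seed=9)
    )


class TestEvaluate:

    def test_identity_assembly_is_perfect(self, genome):
        ref, regions = genome
        asm = identity_assembly(ref, 3)
        records, verdicts = evaluate(ref, asm, toy_align(ref, asm), regions)
        r = records[0]
        assert r.genome_region == "all"
        assert r.representation == 1.0
        assert r.mismatch_rate == r.indel_rate == r.misassembly_rate == 0.0
        assert r.n_gaps == r.total_gap_bases == 0
        assert r.unaligned_contigs == 0
        assert all(v.status == "ALIGNED" for v in verdicts.values())

    def test_region_records_sorted_after_all(self, genome):
        ref, regions = genome
        asm = identity_assembly(ref, 3)
        records, _ = evaluate(ref, asm, toy_align(ref, asm), regions)
        names = [r.genome_region for r in records]
        assert names[0] == "all"
        assert names[1:] == sorted(names[1:])

    def test_conservation_law_per_region(self, genome):
        ref, regions = genome
        asm = identity_assembly(ref, 4)
        records, _ = evaluate(ref, asm, toy_align(ref, asm), regions)
        from asmgrade.fidelity_metrics import regions_to_map

        for rec in records:
            rmap = (
                genome_map(ref)
                if rec.genome_region == "all"
                else regions_to_map(regions, rec.genome_region)
            )
            region_len = sum(interval_total(v) for v in rmap.values())
            covered = round(rec.representation * region_len)
            assert covered + rec.total_gap_bases == region_len

    def test_empty_alignments_zero_record(self, genome):
        ref, regions = genome
        asm = identity_assembly(ref, 3)
        records, verdicts = evaluate(ref, asm, [], regions)
        r = records[0]
        assert r.representation == 0.0
        assert r.unaligned_contigs == 3
        assert all(v.status == "UNALIGNED" for v in verdicts.values())

    def test_region_aligned_bases_bounded_by_all(self, genome):
        ref, regions = genome
        asm = identity_assembly(ref, 3)
        blocks = toy_align(ref, asm)
        from asmgrade.fidelity_metrics import regions_to_map

        _, _, _, all_aligned = compute_error_rates(blocks, genome_map(ref))
        for klass in {"gene", "repeat"}:
            _, _, _, aligned = compute_error_rates(
                blocks, regions_to_map(regions, klass)
            )
            assert aligned <= all_aligned

    def test_unknown_reference_id_rejected(self, genome):
        ref, _ = genome
        asm = identity_assembly(ref, 2)
        bad = [block(0, 100, 0, 100, ref="chrX", qry="scaffold_0")]
        with pytest.raises(ValueError, match="chrX"):
            evaluate(ref, asm, bad)

    def test_ambiguous_bases_counts_assembly_n(self):
        ref = ReferenceGenome({"chr1": "ACGTACGTAC" * 100})
        asm = split_scaffolds(
            AssemblySet(scaffolds={"s": "ACGTACGTAC" * 50 + "N" * 30})
        )
        records, _ = evaluate(ref, asm, toy_align(ref, asm))
        assert records[0].ambiguous_bases == 30
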