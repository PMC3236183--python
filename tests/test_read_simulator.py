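"""Read simulation: planning, placement, error models, FASTQ output."""

import math

import numpy as np
import pytest

from asmgrade import (
    ErrorModelParams,
    GenomePlan,
    ReadDatasetSpec,
    apply_454_errors,
    apply_edits,
    apply_illumina_errors,
    generate_reads,
    make_toy_genome,
    plan_dataset,
    sample_insert,
    simulate,
)
from asmgrade.read_simulator import expected_illumina_subs
from asmgrade.sequence_io import ReferenceGenome, reverse_complement


def zero_spec(**kw):
    defaults = dict(
        platform="ILLUMINA",
        read_length=75,
        paired=True,
        insert_mean=500.0,
        coverage=10.0,
        seed=0,
        error_params=ErrorModelParams.zero(),
        name="t",
    )
    defaults.update(kw)
    return ReadDatasetSpec(**defaults)


class TestPlanning:
    @pytest.mark.parametrize(
        "genome,cov,length,paired,expected",
        [
            (1_000_000, 40, 75, True, 533_334),  # rounded up to even pairs
            (100_000, 16, 500, False, 3_200),
            (100, 1, 75, False, 2),
        ],
    )
    def test_read_counts(self, genome, cov, length, paired, expected):
        spec = zero_spec(
            read_length=length,
            coverage=cov,
            paired=paired,
            insert_mean=4 * length,
        )
        assert plan_dataset(spec, genome) == expected

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            zero_spec(coverage=0)

    def test_insert_shorter_than_two_reads_rejected(self):
        with pytest.raises(ValueError, match="insert_mean"):
            zero_spec(read_length=500, insert_mean=600)

    def test_small_454_insert_is_illumina_only(self):
        with pytest.raises(ValueError, match="Illumina-only"):
            zero_spec(platform="LS454", read_length=100, insert_mean=500)


class TestSampleInsert:
    def test_degenerate_sd_gives_fixed_insert(self):
        ref = ReferenceGenome({"r": "ACGT" * 250})
        spec = zero_spec(insert_mean=500.0, insert_sd=0.0, read_length=100)
        rng = np.random.default_rng(0)
        starts = set()
        for _ in range(500):
            sid, start, ins, strand = sample_insert(spec, ref, rng)
            assert ins == 500
            assert 0 <= start <= 500
            starts.add(start)
        assert len(starts) > 100  # start really varies across placements

    def test_impossible_insert_is_hard_error(self):
        ref = ReferenceGenome({"r": "ACGT" * 2500})  # 10 kb
        spec = zero_spec(insert_mean=40_000.0, read_length=100)
        with pytest.raises(ValueError, match="minimum insert"):
            sample_insert(spec, ref, np.random.default_rng(0))

    def test_reference_choice_proportional_to_length(self):
        rng = np.random.default_rng(1)
        seqs = {
            "big": "".join(rng.choice(list("ACGT"), 900)),
            "small": "".join(rng.choice(list("ACGT"), 100)),
        }
        ref = ReferenceGenome(seqs)
        spec = zero_spec(read_length=30, insert_mean=60.0, insert_sd=0.0)
        draws = [sample_insert(spec, ref, rng)[0] for _ in range(10_000)]
        frac_big = draws.count("big") / len(draws)
        # binomial(10^4, 0.9): 3 sigma ~ 0.009
        assert abs(frac_big - 0.9) < 0.009


class TestErrorModels:
    def test_zero_rates_are_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        assert apply_illumina_errors(seq, ErrorModelParams.zero(), rng) == (seq, [])
        assert apply_454_errors(seq, ErrorModelParams.zero(), rng) == (seq, [])

    def test_illumina_ramp_mean_matches_closed_form(self):
        params = ErrorModelParams(
            illumina_sub_rate_start=0.001, illumina_sub_rate_end=0.01
        )
        expected = expected_illumina_subs(params, 100)
        assert math.isclose(expected, 0.55, rel_tol=1e-9)
        rng = np.random.default_rng(42)
        seq = "ACGT" * 25
        n = 20_000
        total = sum(len(apply_illumina_errors(seq, params, rng)[1]) for _ in range(n))
        sigma = math.sqrt(expected / n)  # Poisson-binomial bound
        assert abs(total / n - expected) < 3 * sigma

    def test_454_homopolymer_bernoulli(self):
        params = ErrorModelParams(
            ls454_base_sub_rate=0.0, ls454_homopolymer_slope=0.05
        )
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(bool(apply_454_errors("AAAAAA", params, rng)[1]) for _ in range(n))
        p = 0.30  # min(1, 6 x 0.05)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_454_indel_changes_length_by_one(self):
        params = ErrorModelParams(ls454_base_sub_rate=0.0, ls454_homopolymer_slope=1.0)
        rng = np.random.default_rng(3)
        out, edits = apply_454_errors("CCAAAACC", params, rng)
        assert len(edits) >= 1
        n_ins = sum(1 for _, a, _b in edits if a == "-")
        n_del = sum(1 for _, _a, b in edits if b == "-")
        assert len(out) == 8 + n_ins - n_del

    def test_determinism_under_seed(self):
        params = ErrorModelParams()
        seq = "ACGTTGCA" * 10
        a = apply_illumina_errors(seq, params, np.random.default_rng(5))
        b = apply_illumina_errors(seq, params, np.random.default_rng(5))
        assert a == b


@pytest.fixture(scope="module")
def genome():
    return make_toy_genome(GenomePlan(length=30_000, seed=4))[0]


class TestSimulate:

    def test_zero_error_reads_are_reference_substrings(self, genome):
        spec = zero_spec(coverage=3, insert_mean=800.0, seed=2)
        for r in generate_reads(genome, spec):
            sub = genome[r.ref_id][r.start : r.start + spec.read_length]
            if r.strand == "-":
                sub = reverse_complement(sub)
            assert sub == r.sequence
            assert r.edits == []

    def test_edit_replay_reproduces_read(self, genome):
        spec = zero_spec(coverage=2, seed=8, error_params=ErrorModelParams())
        for r in generate_reads(genome, spec):
            sub = genome[r.ref_id][r.start : r.start + spec.read_length]
            if r.strand == "-":
                sub = reverse_complement(sub)
            assert apply_edits(sub, r.edits) == r.sequence

    def test_coverage_conservation(self, genome):
        spec = zero_spec(coverage=8, seed=1)
        bases = sum(len(r.sequence) for r in generate_reads(genome, spec))
        target = 8 * genome.total_length
        assert target <= bases <= target + 2 * spec.read_length

    def test_fastq_outputs_and_byte_determinism(self, genome, tmp_path):
        spec = zero_spec(coverage=1, seed=6)
        p1 = simulate(genome, spec, tmp_path / "a")
        p2 = simulate(genome, spec, tmp_path / "b")
        fq_a = (tmp_path / "a_1.fastq").read_bytes()
        fq_b = (tmp_path / "b_1.fastq").read_bytes()
        assert fq_a == fq_b
        assert (tmp_path / "a_2.fastq").exists()
        lines = (tmp_path / "a_1.fastq").read_text().splitlines()
        assert lines[0].startswith("@t_p0/1")
        assert set(lines[3]) == {"?"}  # constant Q30 placeholder
        truth = (tmp_path / "a_truth.tsv").read_text().splitlines()
        assert truth[0].split("\t") == ["read_id", "ref_id", "start", "strand", "edits"]
        assert len(truth) - 1 == len(lines) // 4 * 2

    def test_fragment_dataset_single_file(self, genome, tmp_path):
        spec = zero_spec(paired=False, platform="LS454", read_length=500,
                         insert_mean=2000.0, coverage=2, seed=3)
        paths = simulate(genome, spec, tmp_path / "frag")
        assert "fastq" in paths and "fastq_1" not in paths
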