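import pytest

from asmgrade import GenomePlan, make_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    """50 kb seeded genome with one repeat family and gene annotations."""
    return make_toy_genome(
        GenomePlan(
            length=50_000,
            gc=0.43,
            repeat_blocks=[(600, 3, 0.02)],
            gene_density=1.0,
            seed=1,
        )
    )
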