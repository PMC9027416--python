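import pytest

from mitobench import compare_assembly, generate_reference
from mitobench.synthetic_data import GenomeSpec


@pytest.fixture(scope="session")
def mitogenome():
    """Full-size synthetic reference and gene track (fixed seed)."""
    return generate_reference(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """A compact circular genome for alignment-heavy tests."""
    return generate_reference(
        GenomeSpec(seed=5, length=6000, n_pcg=5, n_trna=8, n_rrna=1)
    )


@pytest.fixture(scope="session")
def small_self_comparison(small_genome):
    """The small reference benchmarked against itself (zero errors)."""
    ref, track = small_genome
    assembly = ref.with_seq(ref.seq, id="self_copy")
    return compare_assembly(ref, assembly, track)
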