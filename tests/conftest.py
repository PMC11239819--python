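import pytest

from cellsafety import synthetic
from cellsafety.variants import VariantKey


@pytest.fixture(scope="session")
def cohort_sim():
    """Default synthetic cohort (5,000 variants, depth 40, seed 0)."""
    return synthetic.simulate_cohort(synthetic.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def amplicon_spec():
    return synthetic.default_amplicon_spec(seed=0)


@pytest.fixture
def key_factory():
    def make(pos=100, ref="A", alt="G", chrom="chr1"):
        return VariantKey(chrom, pos, ref, alt)
    return make
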