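import pytest

from mesoni.synthetic_data import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default-spec synthetic genome with its truth table."""
    return make_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome_batch():
    """100 synthetic genomes across varied specs (shared by the acceptance
    recovery criteria; generation is deterministic)."""
    batch = []
    for s in range(100):
        spec = GenomeSpec(
            seed=s,
            insertion_len=[0, 180, 573, 588][s % 4],
            orf2a_len=3300 + 150 * (s % 2),
            utr5_len=360 + 6 * (s % 3),
            term3_len=1790 + 7 * (s % 2),
        )
        batch.append(make_genome(spec))
    return batch
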