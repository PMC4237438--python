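import pytest

from peaklab.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset shared across tests (read-only)."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, sequence-free dataset for quick structural checks."""
    return generate(
        SyntheticConfig(
            n_chroms=2, chrom_length=400_000, n_genes=10, n_peaks=30,
            replicate_private=5, n_interactions=20, with_sequence=False,
            seed=7,
        )
    )
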