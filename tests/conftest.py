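import pytest

from tripflow.synthetic_data import SyntheticConfig, generate_truth


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_clones=25,
        seed=7,
        n_tf_tracks=3,
        n_states=5,
        reads_per_barcode=100,
        trip_reads_per_barcode=30,
        cells_per_clone=4000,
        chrom_lengths=(("chr1", 2_000_000), ("chr2", 2_000_000)),
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)
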