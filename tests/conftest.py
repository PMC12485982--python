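import numpy as np
import pytest

from procap_atlas import GeneAnnotation, SignalTrack, TruthConfig, simulate_dataset


def make_track(entries, end_type="five_prime"):
    """Build a SignalTrack from {(chrom, strand): {pos: count}}."""
    t = SignalTrack(end_type)
    for (chrom, strand), d in entries.items():
        for pos, count in d.items():
            t.add(chrom, strand, pos, count)
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(TruthConfig(seed=0))


@pytest.fixture
def toy_genes():
    return GeneAnnotation.from_records(
        [
            ("geneA", "chr1", 10_000, 30_000, "+"),
            ("geneB", "chr1", 50_000, 70_000, "-"),
            ("geneC", "chr2", 10_000, 25_000, "+"),
        ]
    )
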