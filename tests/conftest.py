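import numpy as np
import pandas as pd
import pytest

from saltmarsh.tables import CountTable, PairedCommunityTable


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples."""
    return CountTable(["t1", "t2", "t3"], ["s1", "s2"],
                      np.array([[5, 0], [3, 7], [0, 2]]))


def make_paired(dna, rna, sample_ids=None, metadata=None):
    dna = np.atleast_2d(np.asarray(dna))
    rna = np.atleast_2d(np.asarray(rna))
    taxa = [f"t{i}" for i in range(dna.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(dna.shape[1])]
    return PairedCommunityTable(taxa, samples, dna, rna, metadata)


@pytest.fixture
def random_paired_factory():
    """Random small paired tables for property checks."""

    def make(seed, n_taxa=50, n_samples=10, max_count=40):
        rng = np.random.default_rng(seed)
        dna = rng.integers(0, max_count, (n_taxa, n_samples))
        rna = rng.integers(0, max_count, (n_taxa, n_samples))
        return make_paired(dna, rna)

    return make


@pytest.fixture
def grouped_metadata():
    def make(sample_ids, treatments):
        return pd.DataFrame({"treatment": treatments},
                            index=pd.Index(sample_ids, name="sample_id"))

    return make
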