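import numpy as np
import pytest
from hypothesis import settings

import codonvol as cv

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def code():
    return cv.standard_code()


@pytest.fixture(scope="session")
def small_genome():
    """A 200-gene mutational-bias-only genome shared by unit tests."""
    spec = cv.SyntheticGenomeSpec(n_genes=200, min_codons=34, max_codons=200,
                                  gc3_bias=0.6, gc3_sd=0.12, seed=101)
    return cv.generate_genome(spec)


@pytest.fixture(scope="session")
def genome_freqs(small_genome):
    return cv.GenomeCodonFrequencies.from_sequences(small_genome.sequences)
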