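import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from barclust import Params, default_design


@pytest.fixture(scope="session")
def design():
    """Standard synthetic dual-barcode amplicon (25-nt barcodes, 110-codon ORF)."""
    return default_design()


@pytest.fixture(scope="session")
def single_locus_design():
    return default_design(n_loci=1)


@pytest.fixture(scope="session")
def small_design():
    """A shorter amplicon (10-nt barcodes, 20 codons) for fast unit tests."""
    return default_design(barcode_len=10, n_codons=20, seed=11)


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
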