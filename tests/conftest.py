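import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wildsoy import synthdata as sd


@pytest.fixture(scope="session")
def small_reference():
    """1-chromosome 300 Kb reference with TEs and genes (shared, read-only)."""
    return sd.generate_reference(1, [300_000], gc=0.4, te_library_size=10,
                                 n_genes=20, n_te_copies=10, seed=11)


@pytest.fixture(scope="session")
def two_chrom_reference():
    return sd.generate_reference(2, [1_000_000, 800_000], gc=0.35, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
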