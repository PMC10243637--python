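import numpy as np
import pytest

from pirnakit.core import LibraryStats


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def stats_1m():
    """A library of one million genome mappers (CPM scale = raw counts)."""
    return LibraryStats(total_genome_mappers=1e6, genome_unique_mappers=8e5)
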