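import numpy as np
import pytest

import espan
from espan.strand_io import StrandCoverage


@pytest.fixture(scope="session")
def tiny_config():
    """Three closely spaced origins on a 180 kb chromosome; fast to simulate."""
    return espan.default_config(
        n_origins=3, origin_spacing=60_000, depth=20_000, seed=0
    )


@pytest.fixture(scope="session")
def tiny_layout(tiny_config):
    return espan.build_layout(tiny_config)


@pytest.fixture(scope="session")
def tiny_state(tiny_config, tiny_layout):
    return espan.simulate_replication(tiny_layout, tiny_config)


@pytest.fixture()
def make_coverage():
    """Factory for hand-built StrandCoverage objects."""

    def _make(watson, crick, bin_width=500, library_size=None, chrom="chrSim",
              sample="test", replicate=0):
        watson = np.asarray(watson, dtype=np.int64)
        crick = np.asarray(crick, dtype=np.int64)
        if library_size is None:
            library_size = int(watson.sum() + crick.sum())
        return StrandCoverage(
            chrom=chrom,
            chrom_length=len(watson) * bin_width,
            bin_width=bin_width,
            counts_watson=watson,
            counts_crick=crick,
            library_size=library_size,
            sample=sample,
            replicate=replicate,
        )

    return _make
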