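import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

import hicspring as hs


@pytest.fixture(scope="session")
def two_chrom_bins():
    """25 kb + 12 kb genome at 10 kb: global bins 0,1,2 | 3,4."""
    return hs.make_bins({"chrA": 25_000, "chrB": 12_000}, 10_000)


@pytest.fixture(scope="session")
def small_table(two_chrom_bins):
    return hs.ContactTable(
        two_chrom_bins,
        pd.DataFrame({"bin_i": [0, 0, 1], "bin_j": [1, 3, 4], "count": [2, 7, 1]}),
    )


@pytest.fixture(scope="session")
def two_cluster_layout():
    """The hand-enumerated two-chromosome territory fixture: two collinear
    triplets 10 units apart."""
    bins = hs.make_bins({"chrA": 20_000, "chrB": 20_000}, 10_000)
    mg = hs.build_multigraph(bins)
    pos = np.array(
        [[0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0], [11, 0, 0], [12, 0, 0]],
        dtype=float,
    )
    state = hs.LayoutState(pos, np.zeros_like(pos))
    return state, mg


@pytest.fixture(scope="session")
def rabl_recovery():
    """One full-circle Rabl recovery shared across structure tests."""
    return hs.full_circle("rabl", seed=0)
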