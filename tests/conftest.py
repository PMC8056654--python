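import numpy as np
import pandas as pd
import pytest

from dignet.ade import ADEDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_reports(pairs, start_id=1):
    """Build an ADEDataset from a list of (drug, adr) tuples."""
    rows = [
        dict(report_id=f"R{start_id + i:06d}", drug=d, adr=a, source="TEST")
        for i, (d, a) in enumerate(pairs)
    ]
    return ADEDataset(pd.DataFrame(rows))


@pytest.fixture
def four_reports():
    return make_reports([("d1", "a1"), ("d1", "a2"), ("d2", "a1"), ("d2", "a2")])
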