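import numpy as np
import pandas as pd
import pytest

from bcflux import OTUTable, SampleKey


@pytest.fixture
def toy_table() -> OTUTable:
    """6 OTUs x 9 samples: 3 compartments (A, S, W) x 3 time points."""
    rng = np.random.default_rng(42)
    sample_ids = [f"{c}{t}" for t in (0, 1, 2) for c in "ASW"]
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(6, 9)),
        index=[f"otu{i}" for i in range(6)],
        columns=sample_ids,
    )
    counts.iloc[0, :] += 1  # no all-zero sample
    metadata = {
        sid: SampleKey(sid[0], int(sid[1:])) for sid in sample_ids
    }
    return OTUTable(counts, metadata)


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"s1": [2, 3, 5], "s2": [1, 0, 4]},
        index=["otu1", "otu2", "otu3"],
    )


def make_table(columns: dict, metadata: dict) -> OTUTable:
    """Build an OTUTable from {sample_id: counts-list} and {sample_id: (comp, t)}."""
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=[f"otu{i}" for i in range(n)])
    meta = {sid: SampleKey(c, t) for sid, (c, t) in metadata.items()}
    return OTUTable(df, meta)


@pytest.fixture
def star_tree_text():
    def _make(ids, length=1.0):
        return "(" + ",".join(f"{i}:{length}" for i in ids) + ");"

    return _make
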