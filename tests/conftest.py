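import io

import numpy as np
import pandas as pd
import pytest

from pdinet import network_from_edges
from pdinet.expression import ExpressionMatrix


@pytest.fixture
def toy_net():
    """Two TFs, two promoters: A->p1, A->p2, B->p1."""
    return network_from_edges([("A", "p1"), ("A", "p2"), ("B", "p1")])


@pytest.fixture
def ffl_net():
    """One feed-forward loop: A regulates B, both regulate p."""
    return network_from_edges([("A", "B"), ("A", "p"), ("B", "p")])


@pytest.fixture
def toy_edge_tsv():
    return io.StringIO("tf\tpromoter\nA\tp1\nA\tp2\nB\tp1\n")


def make_expression(values: dict, tissues=("leaf",), n_times=6, n_reps=3):
    """ExpressionMatrix from gene -> per-(tissue,time,rep) value list."""
    sample_ids, meta_rows = [], []
    times = [0, 0.5, 3, 24, 24.5, 48][:n_times]
    for tis in tissues:
        for t in times:
            for r in range(1, n_reps + 1):
                sid = f"{tis}_t{t:g}_r{r}"
                sample_ids.append(sid)
                phase = "baseline" if t == 0 else ("deprivation" if t <= 24 else "recovery")
                meta_rows.append({"sample_id": sid, "tissue": tis, "phase": phase,
                                  "time_h": float(t), "replicate": r})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    df = pd.DataFrame(
        {g: np.asarray(v, dtype=float) for g, v in values.items()}
    ).T
    df.columns = sample_ids
    return ExpressionMatrix(df, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
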