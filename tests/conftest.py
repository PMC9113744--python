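import numpy as np
import pandas as pd
import pytest

import thermatlas as ta


@pytest.fixture(scope="session")
def toy():
    """The seed-pinned toy experiment: (CountMatrix, sample sheet, truth)."""
    return ta.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_contrasts(toy):
    """Per-condition contrast families on the toy data."""
    cm, sheet, _ = toy
    return {
        10.0: ta.contrast_set(cm, sheet, 10.0),
        34.0: ta.contrast_set(cm, sheet, 34.0),
    }


def make_de_table(calls, tissue="T", treat=10.0, ctrl=22.0):
    """Hand-build a DETable from {gene: (log2fc, p_value, call)}."""
    genes = list(calls)
    df = pd.DataFrame(
        {
            "log2fc": [calls[g][0] for g in genes],
            "p_value": [calls[g][1] for g in genes],
            "mean_logcpm": 5.0,
            "call": [calls[g][2] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    df["p_adj"] = df["p_value"]
    return ta.DETable(tissue, treat, ctrl, df)


@pytest.fixture
def make_det():
    return make_de_table
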