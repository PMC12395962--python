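import numpy as np
import pandas as pd
import pytest

from spexkit.types import make_cell_table


@pytest.fixture
def six_cell_table():
    """Three A cells and three B cells at hand-checkable positions.

    At radius 1.5: A(0,0) neighbors B(1,0) and B(0,1); A(5,5) is isolated;
    A(10,0) neighbors B(10,1) only.
    """
    coords = np.array(
        [[0, 0], [5, 5], [10, 0], [1, 0], [0, 1], [10, 1]], dtype=float
    )
    types = ["A", "A", "A", "B", "B", "B"]
    return make_cell_table(
        X=np.zeros((6, 1)),
        coords=coords,
        feature_names=["m"],
        cell_type=pd.Categorical(types),
    )


def brute_force_local_clq(coords, labels, type_a, type_b, radius,
                          kernel="uniform", sigma=None):
    """Independent double-loop LCLQ oracle (no shared code with the package)."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    n_b = int((labels == type_b).sum())
    n_b_eff = n_b - 1 if type_a == type_b else n_b
    expected = n_b_eff / (n - 1)
    out = np.full(n, np.nan)
    for i in range(n):
        if labels[i] != type_a:
            continue
        num = den = 0.0
        for j in range(n):
            if j == i:
                continue
            d = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            if d > radius:
                continue
            w = 1.0 if kernel == "uniform" else np.exp(-d * d / (2 * sigma * sigma))
            den += w
            if labels[j] == type_b:
                num += w
        if den > 0:
            out[i] = (num / den) / expected
    return out
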