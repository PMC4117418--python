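import numpy as np
import pytest

from ccast import ExpressionTable


@pytest.fixture
def two_blobs():
    """Two well-separated 2-D blobs of 20 cells each, with truth labels."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.3, size=(20, 2))
    b = rng.normal([8.0, 8.0], 0.3, size=(20, 2))
    table = ExpressionTable(
        values=np.vstack([a, b]),
        marker_names=("M1", "M2"),
        transformed=True,
    )
    labels = np.repeat([0, 1], 20)
    return table, labels


def make_table(values, names=None, transformed=True):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1 and names is None:
        values = values.T
    if names is None:
        names = tuple(f"M{k+1}" for k in range(values.shape[1]))
    return ExpressionTable(values=values, marker_names=tuple(names), transformed=transformed)
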