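import numpy as np
import pandas as pd
import pytest

from plsdex import ExpressionMatrix, SampleLabels


@pytest.fixture
def small_matrix():
    """4 probes x 6 samples with an obvious class difference in P1/P2."""
    data = pd.DataFrame(
        {
            "s1": [8.0, 4.0, 5.0, 7.0],
            "s2": [8.2, 4.1, 5.2, 7.1],
            "s3": [8.1, 3.9, 4.8, 6.9],
            "s4": [6.0, 6.0, 5.1, 7.2],
            "s5": [6.1, 6.2, 4.9, 7.0],
            "s6": [5.9, 6.1, 5.0, 6.8],
        },
        index=["P1", "P2", "P3", "P4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_labels():
    return SampleLabels(
        pd.Series([1, 1, 1, 0, 0, 0], index=[f"s{i}" for i in range(1, 7)]),
        group_names={1: "patient", 0: "control"},
    )


def random_instance(rng, n=None, p=None):
    """A random autoscaled (X, y) pair with both classes present."""
    n = n or int(rng.integers(4, 11))
    p = p or int(rng.integers(2, 11))
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n1 = int(rng.integers(2, n - 1))
    y01 = np.array([1.0] * n1 + [0.0] * (n - n1))
    rng.shuffle(y01)
    return X, y01 - y01.mean()
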